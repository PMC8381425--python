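"""Perpendicular distance field, reflection filter, regions, median JSW."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kneejsw.errors import MeasurementError, ValidationError
from kneejsw.jsw3d import (
    DistanceSampleSet,
    define_compartments,
    label_compartments,
    median_jsw,
    perpendicular_distance_field,
    reflection_filter,
)
from kneejsw.phantom import PhantomSpec, make_phantom
from kneejsw.segmentation import SurfacePair, surface_normals, surfaces_from_phantom

from conftest import plate_spec


def pair_from_fields(x, y, z_t, z_f):
    return SurfacePair(
        x,
        y,
        z_t,
        z_f,
        surface_normals(x, y, z_t, upward=True),
        surface_normals(x, y, z_f, upward=False),
        (float(x[1] - x[0]), float(y[1] - y[0])),
    )


def brute_force_ray_march(origin, direction, z_f_func, max_distance=20.0, step=1e-4):
    """Independent fine-march oracle for the first femoral crossing."""
    t = 0.0
    while t <= max_distance:
        p = origin + t * direction
        zf = z_f_func(p[0], p[1])
        if np.isnan(zf):
            return np.nan
        if p[2] >= zf:
            return t
        t += step
    return np.nan


class TestPerpendicularDistance:
    def test_parallel_plates_give_plate_gap(self):
        ph = make_phantom(plate_spec(thickness=1.75, gap=0.5))  # 4.0 mm
        samples = perpendicular_distance_field(surfaces_from_phantom(ph))
        assert samples.hit.all()
        assert np.allclose(samples.distance, 4.0, atol=1e-3)

    def test_tilted_tibia_under_horizontal_femur_matches_march_oracle(self):
        """Ray along the tilted tibial normal meets a horizontal femoral
        plane at length g / cos(theta) — confirmed by a brute-force
        fine-march oracle."""
        theta = np.deg2rad(10.0)
        x = np.arange(0.0, 41.0)
        y = np.arange(0.0, 31.0)
        xx, _ = np.meshgrid(x, y, indexing="ij")
        z_t = np.tan(theta) * (xx - 20.0)
        g = 5.0
        z_f = np.full_like(z_t, g)  # horizontal plane at z = g
        pair = pair_from_fields(x, y, z_t, z_f)
        samples = perpendicular_distance_field(pair, max_distance=12.0)
        centre = (samples.x == 20.0) & (samples.y == 15.0)
        measured = samples.distance[centre][0]

        origin = np.array([20.0, 15.0, 0.0])
        n = np.array([-np.tan(theta), 0.0, 1.0])
        n /= np.linalg.norm(n)
        oracle = brute_force_ray_march(origin, n, lambda _x, _y: g)
        assert measured == pytest.approx(oracle, abs=1e-3)
        assert measured == pytest.approx(g / np.cos(theta), abs=1e-3)

    def test_parallel_tilted_plates_follow_cosine_law(self):
        """For parallel tilted plates at vertical gap g the perpendicular
        distance is g cos(theta)."""
        theta = np.deg2rad(10.0)
        x = np.arange(0.0, 41.0)
        y = np.arange(0.0, 31.0)
        xx, _ = np.meshgrid(x, y, indexing="ij")
        g = 5.0
        z_t = np.tan(theta) * (xx - 20.0)
        z_f = z_t + g
        pair = pair_from_fields(x, y, z_t, z_f)
        samples = perpendicular_distance_field(pair, max_distance=12.0)
        inner = (samples.x > 5) & (samples.x < 35) & samples.hit
        assert np.allclose(samples.distance[inner], g * np.cos(theta), atol=1e-3)

    def test_rays_leaving_truncated_femur_miss(self):
        ph = make_phantom(plate_spec())
        pair = surfaces_from_phantom(ph)
        pair.z_femur[pair.x > 40.0, :] = np.nan
        samples = perpendicular_distance_field(pair)
        assert not samples.hit[samples.x > 40.0].any()
        assert samples.hit[samples.x < 40.0].all()

    @pytest.mark.parametrize("step,max_distance", [(0.0, 10.0), (-1.0, 10.0), (11.0, 10.0)])
    def test_invalid_march_parameters(self, step, max_distance):
        ph = make_phantom(plate_spec())
        with pytest.raises(ValidationError):
            perpendicular_distance_field(
                surfaces_from_phantom(ph), max_distance=max_distance, step=step
            )


class TestReflectionFilter:
    def test_parallel_plates_fully_reflected(self):
        ph = make_phantom(plate_spec())
        pair = surfaces_from_phantom(ph)
        samples = reflection_filter(perpendicular_distance_field(pair), pair)
        assert samples.reflected[samples.hit].all()

    def test_overhang_rim_samples_not_reflected(self):
        """A tibia much narrower than a strongly curved femoral edge: rim
        rays hit condyle flanks whose return normals point outward, past
        the tibial surface — checked against an exhaustive return march."""
        x = np.arange(0.0, 41.0)
        y = np.arange(0.0, 21.0)
        xx, _ = np.meshgrid(x, y, indexing="ij")
        z_t = np.zeros_like(xx)
        z_t[xx > 20.0] = np.nan  # tibia exists only for x <= 20
        # femoral surface curving steeply upward beyond the tibial edge
        z_f = 3.0 + np.where(xx > 18.0, ((xx - 18.0) / 4.0) ** 2 * 20.0, 0.0)
        pair = pair_from_fields(x, y, z_t, z_f)
        samples = reflection_filter(
            perpendicular_distance_field(pair, max_distance=30.0), pair, max_distance=30.0
        )
        flat = samples.reflected[samples.hit & (samples.x < 15.0)]
        assert flat.all()
        rim = samples.hit & (samples.x >= 19.0) & (samples.x <= 20.0)
        assert not samples.reflected[rim].all()

    def test_short_max_distance_leaves_nothing_reflected(self):
        ph = make_phantom(plate_spec(thickness=1.75, gap=0.5))  # 4 mm gap
        pair = surfaces_from_phantom(ph)
        samples = perpendicular_distance_field(pair, max_distance=2.0, step=0.2)
        assert not samples.hit.any()
        regions = define_compartments(70.0)
        with pytest.raises(MeasurementError):
            median_jsw(samples, regions, "medial")

    def test_pure_filter_adds_nothing_and_keeps_distances(self):
        ph = make_phantom(PhantomSpec(condyle_radius=25.0))
        pair = surfaces_from_phantom(ph)
        before = perpendicular_distance_field(pair)
        after = reflection_filter(before, pair)
        assert len(after) == len(before)
        assert np.array_equal(after.distance, before.distance, equal_nan=True)
        assert np.array_equal(after.hit, before.hit)


class TestCompartmentRegions:
    def test_width_20_gives_printed_fractions(self):
        regions = define_compartments(20.0)
        lo, hi = regions.medial
        assert hi - lo == pytest.approx(3.0)  # 3/20 of 20
        assert lo == pytest.approx(8.0 / 3.0)  # 2/15 of 20

    def test_width_100_medial_interval(self):
        regions = define_compartments(100.0)
        assert regions.medial[0] == pytest.approx(13.3333, abs=1e-3)
        assert regions.medial[1] == pytest.approx(28.3333, abs=1e-3)

    @given(width=st.floats(min_value=1e-3, max_value=1e4))
    def test_regions_disjoint_and_inside_joint(self, width):
        regions = define_compartments(width)
        m_lo, m_hi = regions.medial
        l_lo, l_hi = regions.lateral
        assert 0 <= m_lo < m_hi <= l_lo < l_hi <= width
        # o + w = (2/15 + 3/20) W < W/2 so the regions can never meet
        assert m_hi < width / 2 < l_lo

    def test_side_of_medial_mirrors_regions(self):
        left = define_compartments(60.0, "left")
        right = define_compartments(60.0, "right")
        assert left.medial == right.lateral
        assert left.lateral == right.medial

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            define_compartments(0.0)


class TestMedianJsw:
    def test_parallel_plates_median_equals_mean(self):
        ph = make_phantom(plate_spec(thickness=1.75, gap=0.5))
        pair = surfaces_from_phantom(ph)
        samples = reflection_filter(perpendicular_distance_field(pair), pair)
        regions = define_compartments(70.0)
        res = median_jsw(samples, regions, "medial")
        assert res.median_jsw == pytest.approx(4.0, abs=1e-3)
        assert res.mean_jsw == pytest.approx(4.0, abs=1e-3)
        assert res.included_area_fraction == pytest.approx(1.0)

    def test_median_robust_to_spike(self):
        """Included distances {3,3,3,3,100}: median 3, mean 22.4 — the
        stated rationale for preferring the median."""
        n = 5
        samples = DistanceSampleSet(
            x=np.full(n, 5.0),
            y=np.arange(n, dtype=float),
            z=np.zeros(n),
            distance=np.array([3.0, 3.0, 3.0, 3.0, 100.0]),
            hit_point=np.zeros((n, 3)),
            hit=np.ones(n, dtype=bool),
            reflected=np.ones(n, dtype=bool),
            compartment=np.full(n, "medial", dtype="<U13"),
            included=np.ones(n, dtype=bool),
        )
        regions = define_compartments(30.0)
        res = median_jsw(samples, regions, "medial", min_count=5)
        assert res.median_jsw == pytest.approx(3.0)
        assert res.mean_jsw == pytest.approx(22.4)

    def test_sphere_on_plane_median_matches_analytic_percentile(self):
        """Median over the medial region equals the 50th percentile of the
        analytic sphere-over-plane distance map, within one grid step."""
        R = 30.0
        spec = plate_spec(
            thickness=1.0, gap=0.5, condyle_radius=R, step=0.5, extent_y=30.0
        )
        ph = make_phantom(spec)
        pair = surfaces_from_phantom(ph)
        samples = reflection_filter(
            perpendicular_distance_field(pair, max_distance=30.0), pair, max_distance=30.0
        )
        regions = define_compartments(70.0)
        res = median_jsw(samples, regions, "medial")

        # dense analytic oracle: vertical gap map of the same geometry
        # (flat tibia, so the perpendicular distance is the vertical gap)
        xs = np.arange(0.0, 70.0 + 1e-9, 0.125)
        ys = np.arange(0.0, 30.0 + 1e-9, 0.125)
        xg, yg = np.meshgrid(xs, ys, indexing="ij")
        r = np.minimum(
            np.hypot(xg - 70 / 6, yg - 15.0), np.hypot(xg - 5 * 70 / 6, yg - 15.0)
        )
        r_eff = np.minimum(r, 0.95 * R)
        analytic = 2.5 + R - np.sqrt(R**2 - r_eff**2)
        lo, hi = regions.medial
        sel = (xg >= lo) & (xg <= hi)
        assert res.median_jsw == pytest.approx(
            np.percentile(analytic[sel], 50), abs=spec.step
        )

    def test_monotone_under_uniform_gap_inflation(self):
        """Inflating the gap by delta raises every twice-included distance
        by at least delta * cos(max femoral slope), and the median too."""
        ph = make_phantom(
            PhantomSpec(condyle_radius=25.0, plateau_tilt_deg=3.0, extent_y=30.0)
        )
        pair = surfaces_from_phantom(ph)
        regions = define_compartments(70.0)
        s1 = reflection_filter(
            perpendicular_distance_field(pair, max_distance=30.0), pair, max_distance=30.0
        )
        res1 = median_jsw(s1, regions, "medial")
        delta = 0.7
        pair2 = surfaces_from_phantom(ph)
        pair2.z_femur += delta
        s2 = reflection_filter(
            perpendicular_distance_field(pair2, max_distance=30.0),
            pair2,
            max_distance=30.0,
        )
        res2 = median_jsw(s2, regions, "medial")
        gx, gy = np.gradient(ph.z_femur, ph.x, ph.y)
        cos_max = 1.0 / np.sqrt(1.0 + np.nanmax(np.hypot(gx, gy)) ** 2)
        common = s1.hit & s2.hit & s1.reflected & s2.reflected
        assert np.all(s2.distance[common] - s1.distance[common] >= delta * cos_max - 1e-9)
        assert res2.median_jsw >= res1.median_jsw + delta * cos_max

    def test_label_compartments_sets_included(self):
        ph = make_phantom(plate_spec())
        pair = surfaces_from_phantom(ph)
        samples = reflection_filter(perpendicular_distance_field(pair), pair)
        regions = define_compartments(70.0)
        label_compartments(samples, regions)
        assert set(np.unique(samples.compartment)) == {"", "medial", "lateral"}
        assert samples.included.sum() == ((samples.compartment != "") & samples.hit).sum()
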