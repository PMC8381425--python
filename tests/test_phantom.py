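"""Phantom construction, loading, rendering and cohort simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kneejsw.errors import ValidationError
from kneejsw.phantom import (
    PhantomSpec,
    apply_load,
    make_phantom,
    observe_mri_thickness,
    render_ct,
    simulate_cohort,
)

from conftest import plate_spec


class TestMakePhantom:
    def test_parallel_plates_uniform_gap(self):
        ph = make_phantom(plate_spec(thickness=1.0, gap=0.5))
        assert np.allclose(ph.gap, 2.5)
        assert not ph.loaded

    def test_thinner_medial_cartilage_gives_smaller_medial_gap(self):
        spec = PhantomSpec(
            cartilage_tibial={"medial": 0.5, "lateral": 1.5},
            cartilage_femoral={"medial": 1.0, "lateral": 1.0},
        )
        ph = make_phantom(spec)
        med = ph.gap[ph.compartments == "medial"].mean()
        lat = ph.gap[ph.compartments == "lateral"].mean()
        assert med < lat

    def test_condyle_sagitta_matches_circle_over_plane(self):
        """Gap along the condyle midline follows the circle-over-plane form.

        Closed form: gap(x) = g0 + R - sqrt(R^2 - (x - x0)^2), checked
        against a dense-grid numeric minimum-distance oracle.
        """
        R = 30.0
        spec = plate_spec(thickness=1.0, gap=0.5, condyle_radius=R, step=0.5)
        ph = make_phantom(spec)
        x0 = spec.extent_x / 6  # medial condyle apex
        y0 = spec.extent_y / 2
        iy = np.argmin(np.abs(ph.y - y0))
        near = np.abs(ph.x - x0) < 8
        g0 = 2.5  # c_t + c_f + residual gap at the apex
        expected = g0 + R - np.sqrt(R**2 - (ph.x[near] - x0) ** 2)
        assert np.allclose(ph.gap[near, iy], expected, atol=1e-9)

        # numeric oracle: sagitta of a sphere surface sampled densely
        xs = np.linspace(x0 - 8, x0 + 8, 4001)
        sphere_z = R - np.sqrt(R**2 - (xs - x0) ** 2)
        for xq in ph.x[near][::4]:
            j = np.argmin(np.abs(xs - xq))
            assert abs((g0 + sphere_z[j]) - g0 - R + np.sqrt(R**2 - (xq - x0) ** 2)) < 1e-3

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"step": 0.0},
            {"step": -1.0},
            {"cartilage_tibial": {"medial": -0.1, "lateral": 1.0}},
            {"deformability": 1.0},
            {"extrusion_grade": 4},
            {"residual_gap": -0.5},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(
            cartilage_tibial={"medial": 1.0, "lateral": 1.0},
            cartilage_femoral={"medial": 1.0, "lateral": 1.0},
        )
        base.update(kwargs)
        with pytest.raises(ValidationError):
            PhantomSpec(**base)


class TestApplyLoad:
    def test_zero_deformability_closes_residual_gap_only(self):
        ph = make_phantom(plate_spec(thickness=1.0, gap=0.5, deformability=0.0))
        lo = apply_load(ph, 1.0, meniscal_load_share=0.0)
        assert np.allclose(lo.gap, ph.gap - 0.5)
        assert lo.loaded

    def test_zero_load_identity_except_flag(self):
        ph = make_phantom(plate_spec())
        lo = apply_load(ph, 0.0)
        assert lo.loaded
        assert np.array_equal(lo.z_femur, ph.z_femur)
        assert np.array_equal(lo.c_tibia, ph.c_tibia)

    def test_hand_arithmetic_compressed_plates(self):
        """1+1 mm cartilage, zero gap, delta 0.2, full load -> 1.6 mm."""
        ph = make_phantom(plate_spec(thickness=1.0, gap=0.0, deformability=0.2))
        lo = apply_load(ph, 1.0, meniscal_load_share=0.0)
        assert np.allclose(lo.gap, 1.6)

    def test_loaded_gap_never_exceeds_unloaded(self):
        ph = make_phantom(PhantomSpec(condyle_radius=25.0, plateau_tilt_deg=3.0))
        lo = apply_load(ph, 1.0)
        assert np.all(lo.gap <= ph.gap + 1e-12)

    def test_meniscal_load_share_attenuates_compression(self):
        ph = make_phantom(plate_spec(thickness=1.0, gap=0.0, deformability=0.2))
        full = apply_load(ph, 1.0, meniscal_load_share=0.0)
        shared = apply_load(ph, 1.0, meniscal_load_share=0.5)
        assert shared.gap.min() > full.gap.min()

    def test_excessive_compression_rejected(self):
        ph = make_phantom(plate_spec(deformability=0.0))
        with pytest.raises(ValidationError):
            apply_load(ph, 1.0, deformability=1.0)

    def test_double_loading_rejected(self):
        lo = apply_load(make_phantom(plate_spec()), 1.0)
        with pytest.raises(ValidationError):
            apply_load(lo, 1.0)


class TestRenderCt:
    def test_dark_band_height_matches_gap(self):
        ph = make_phantom(plate_spec(thickness=1.75, gap=0.5))  # 4.0 mm gap
        vol = render_ct(ph, spacing=0.5, noise_sd=0.0)
        mid = vol.data[20, 20, :]
        zc = vol.coords(2)
        in_gap = (mid == 0) & (zc > -1) & (zc < 5)
        assert abs(in_gap.sum() - np.ceil(4.0 / 0.5)) <= 1

    def test_threshold_recovers_bone_masks(self):
        ph = make_phantom(plate_spec(thickness=1.75, gap=0.5))
        vol = render_ct(ph, spacing=0.5, noise_sd=0.0)
        zc = vol.coords(2)
        tib_truth = zc[None, None, :] < 0.0  # tibial surface at z=0
        fem_truth = zc[None, None, :] > 4.0
        tib = (vol.data > 500) & (zc[None, None, :] < 2.0)
        fem = (vol.data > 500) & (zc[None, None, :] > 2.0)
        assert np.array_equal(tib, np.broadcast_to(tib_truth, vol.shape))
        assert np.array_equal(fem, np.broadcast_to(fem_truth, vol.shape))

    def test_invalid_spacing_rejected(self):
        ph = make_phantom(plate_spec())
        with pytest.raises(ValidationError):
            render_ct(ph, spacing=0.0)

    def test_coarse_spacing_logs_warning(self, caplog):
        ph = make_phantom(plate_spec(thickness=1.0, gap=0.0))  # 2 mm gap
        with caplog.at_level("WARNING", logger="kneejsw.phantom"):
            render_ct(ph, spacing=1.5)
        assert any("unresolvable" in rec.message for rec in caplog.records)


class TestObserveMri:
    def test_zero_noise_identity(self):
        ph = make_phantom(plate_spec(thickness=2.0))
        c_t, c_f = observe_mri_thickness(ph, 0.0)
        assert np.array_equal(c_t, ph.c_tibia)
        assert np.array_equal(c_f, ph.c_femur)

    def test_mean_absolute_deviation_is_half_normal(self):
        """MAD of Gaussian noise ~= sd * sqrt(2/pi) over a large grid."""
        ph = make_phantom(plate_spec(thickness=2.0, step=0.5))
        c_t, _ = observe_mri_thickness(ph, 0.1, seed=7)
        mad = np.abs(c_t - ph.c_tibia).mean()
        expected = 0.1 * np.sqrt(2 / np.pi)
        assert abs(mad - expected) < 0.005

    def test_loaded_phantom_rejected(self):
        lo = apply_load(make_phantom(plate_spec()), 1.0)
        with pytest.raises(ValidationError):
            observe_mri_thickness(lo, 0.1)

    def test_negative_noise_rejected(self):
        ph = make_phantom(plate_spec())
        with pytest.raises(ValidationError):
            observe_mri_thickness(ph, -0.1)


class TestSimulateCohort:
    def test_zero_effect_zero_sd_gives_zero_true_deltas(self):
        recs = simulate_cohort(5, effect_mean=0.0, effect_sd=0.0, seed=3)
        by_subject = {}
        for r in recs:
            by_subject.setdefault(r.subject, {})[r.timepoint] = r
        for recs_t in by_subject.values():
            d = (
                recs_t["2yr"].true_thickness["medial"]
                - recs_t["baseline"].true_thickness["medial"]
            )
            assert d == pytest.approx(0.0, abs=1e-12)

    def test_mean_true_delta_near_effect(self):
        recs = simulate_cohort(100, effect_mean=0.2, effect_sd=0.1, seed=11)
        by_subject = {}
        for r in recs:
            by_subject.setdefault(r.subject, {})[r.timepoint] = r
        deltas = [
            v["2yr"].true_thickness["medial"] - v["baseline"].true_thickness["medial"]
            for v in by_subject.values()
        ]
        se = 0.1 / np.sqrt(100)
        assert abs(np.mean(deltas) - 0.2) < 3 * se

    def test_no_drift_couples_loaded_and_unloaded_deltas(self):
        """Without deformability drift, weight-bearing and unloaded changes
        correlate almost perfectly at the truth level."""
        recs = simulate_cohort(100, delta_drift_sd=0.0, seed=13)
        by_subject = {}
        for r in recs:
            by_subject.setdefault(r.subject, {})[r.timepoint] = r
        d_load, d_unload = [], []
        for v in by_subject.values():
            sel = v["baseline"].unloaded.compartments == "medial"
            d_unload.append(
                v["2yr"].unloaded.gap[sel].mean() - v["baseline"].unloaded.gap[sel].mean()
            )
            d_load.append(
                v["2yr"].loaded.gap[sel].mean() - v["baseline"].loaded.gap[sel].mean()
            )
        r = np.corrcoef(d_load, d_unload)[0, 1]
        assert r > 0.95

    def test_identical_seeds_identical_cohorts(self):
        a = simulate_cohort(5, seed=99)
        b = simulate_cohort(5, seed=99)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.unloaded.gap, rb.unloaded.gap)
            assert np.array_equal(ra.loaded.gap, rb.loaded.gap)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(1)


@given(scale=st.floats(min_value=0.5, max_value=3.0))
def test_scale_equivariance(scale):
    """Scaling every mm parameter by s scales the gap map by s."""
    base = plate_spec(thickness=1.0, gap=0.5, condyle_radius=25.0)
    ph1 = make_phantom(base)
    scaled = plate_spec(
        thickness=scale,
        gap=0.5 * scale,
        condyle_radius=25.0 * scale,
        extent_x=base.extent_x * scale,
        extent_y=base.extent_y * scale,
        step=base.step * scale,
    )
    ph2 = make_phantom(scaled)
    assert ph2.gap.shape == ph1.gap.shape
    assert np.allclose(ph2.gap, ph1.gap * scale, rtol=1e-9)
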