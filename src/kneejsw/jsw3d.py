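"""3D perpendicular joint space width.

The core measurement: from every defined point of the tibial plateau a ray
is cast along the local surface normal and its first crossing of the
femoral surface located; the Euclidean ray length is the perpendicular
bone-to-bone distance.  Samples are then restricted to mutually opposing
bone — a sample is kept only if the perpendicular cast *back* from its
femoral hit point meets the tibial surface ("reflected"), so that only
joint-space areas where force can be transferred between the bones
contribute.  The median of the remaining distances inside the most
affected compartment's region is the 3D surface median JSW; the median is
preferred over the mean to suppress artificially large bone-to-bone
distances at the joint margins.

Compartment regions follow the digital radiographic analysis convention:
each side's measurement region is 3/20 of the total joint width wide and
its outer border lies 2/15 of the total width inside the joint's outer
border.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import MeasurementError, ValidationError
from .segmentation import SurfacePair

#: KIDA region geometry: width of each side's region and its outer offset,
#: as exact fractions of the total joint width.
REGION_WIDTH_FRACTION = Fraction(3, 20)
OUTER_OFFSET_FRACTION = Fraction(2, 15)

_BISECT_ITERS = 30  # step/2**30 << 1e-4 mm for any sane march step


@dataclass
class DistanceSampleSet:
    """Per-tibial-point perpendicular distance samples (flat arrays)."""

    x: np.ndarray  # (n,) tibial point x (mm)
    y: np.ndarray  # (n,) tibial point y (mm)
    z: np.ndarray  # (n,) tibial surface z (mm)
    distance: np.ndarray  # (n,) perpendicular distance (mm), NaN on miss
    hit_point: np.ndarray  # (n, 3) femoral intersection (mm), NaN on miss
    hit: np.ndarray  # (n,) bool
    reflected: np.ndarray  # (n,) bool, only meaningful where hit
    compartment: np.ndarray  # (n,) '<U13' labels, '' if unassigned
    included: np.ndarray  # (n,) bool: hit & reflected & in a compartment region

    def __len__(self) -> int:
        return self.x.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "distance": self.distance,
                "hit": self.hit,
                "reflected": self.reflected,
                "compartment": self.compartment,
                "included": self.included,
            }
        )


@dataclass
class CompartmentRegions:
    """Medial/lateral measurement intervals across the joint width.

    Intervals are expressed in joint-width coordinates (0 at the medial
    outer border if ``side_of_medial == "left"``, else at the lateral
    border); add the joint's left-edge x to map to absolute positions.
    """

    width: float  # total joint width W (mm)
    side_of_medial: str = "left"
    medial: tuple[float, float] = field(init=False)
    lateral: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError(f"joint width must be > 0, got {self.width}")
        if self.side_of_medial not in ("left", "right"):
            raise ValidationError("side_of_medial must be 'left' or 'right'")
        o = float(OUTER_OFFSET_FRACTION) * self.width
        w = float(REGION_WIDTH_FRACTION) * self.width
        left = (o, o + w)
        right = (self.width - o - w, self.width - o)
        if self.side_of_medial == "left":
            self.medial, self.lateral = left, right
        else:
            self.medial, self.lateral = right, left

    def interval(self, compartment: str) -> tuple[float, float]:
        if compartment == "medial":
            return self.medial
        if compartment == "lateral":
            return self.lateral
        raise ValidationError(f"unknown compartment {compartment!r}")


@dataclass
class JSWResult:
    """Median/mean JSW over included samples of one compartment region."""

    compartment: str
    median_jsw: float  # mm
    mean_jsw: float  # mm
    n_included: int
    included_area_fraction: float  # included / all samples in region


def define_compartments(width: float, side_of_medial: str = "left") -> CompartmentRegions:
    """Medial and lateral measurement regions for a joint of total width W."""
    return CompartmentRegions(width, side_of_medial)


def _femur_interp(pair: SurfacePair) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (pair.x, pair.y), pair.z_femur, bounds_error=False, fill_value=np.nan
    )


def _tibia_interp(pair: SurfacePair) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (pair.x, pair.y), pair.z_tibia, bounds_error=False, fill_value=np.nan
    )


def _march_to_crossing(
    origins: np.ndarray,
    directions: np.ndarray,
    signed_gap,
    max_distance: float,
    step: float,
    bisect: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """March rays until ``signed_gap(points)`` first becomes <= 0.

    ``signed_gap`` maps (m, 3) points to (m,) values, positive on the
    near side of the target surface and NaN outside its domain.  Returns
    (hit mask, ray length), with NaN length on misses.  With ``bisect``
    the crossing is refined to ~1e-4 mm; otherwise the crossing step is
    returned (enough for a boolean reachability test).
    """
    n = origins.shape[0]
    hit = np.zeros(n, dtype=bool)
    t_lo = np.full(n, np.nan)
    t_hi = np.full(n, np.nan)
    alive = np.ones(n, dtype=bool)

    f_prev = signed_gap(origins)
    alive &= ~np.isnan(f_prev)
    # points already at/through the surface count as immediate hits
    touch = alive & (f_prev <= 0)
    hit |= touch
    t_lo[touch] = 0.0
    t_hi[touch] = 0.0
    alive &= ~touch

    t = 0.0
    while t < max_distance and alive.any():
        t_next = min(t + step, max_distance)
        idx = np.nonzero(alive)[0]
        pts = origins[idx] + t_next * directions[idx]
        f = signed_gap(pts)
        crossed = f <= 0
        gone = np.isnan(f)
        hit_idx = idx[crossed & ~gone]
        hit[hit_idx] = True
        t_lo[hit_idx] = t
        t_hi[hit_idx] = t_next
        alive[idx[crossed | gone]] = False
        # keep previous f only for rays still alive; not needed further
        t = t_next

    if bisect and hit.any():
        idx = np.nonzero(hit & (t_hi > t_lo))[0]
        lo = t_lo[idx].copy()
        hi = t_hi[idx].copy()
        for _ in range(_BISECT_ITERS):
            mid = 0.5 * (lo + hi)
            pts = origins[idx] + mid[:, None] * directions[idx]
            f = signed_gap(pts)
            below = (f <= 0) | np.isnan(f)  # ties resolved toward smaller distance
            hi = np.where(below, mid, hi)
            lo = np.where(below, lo, mid)
        t_lo[idx] = lo
        t_hi[idx] = hi

    length = 0.5 * (t_lo + t_hi)
    length[~hit] = np.nan
    return hit, length


def perpendicular_distance_field(
    pair: SurfacePair, max_distance: float = 15.0, step: float = 0.25
) -> DistanceSampleSet:
    """Cast a perpendicular from every defined tibial point to the femur.

    Rays start on the tibial superior surface and travel along the local
    tibial unit normal; the first crossing of the femoral inferior surface
    is located by coarse marching plus bisection (tolerance ~1e-4 mm).
    Rays that exit the defined femoral domain or exceed ``max_distance``
    are misses.
    """
    if max_distance <= 0:
        raise ValidationError("max_distance must be > 0")
    if step <= 0 or step >= max_distance:
        raise ValidationError("march step must satisfy 0 < step < max_distance")

    defined = ~np.isnan(pair.z_tibia)
    ii, jj = np.nonzero(defined)
    origins = np.column_stack(
        [pair.x[ii], pair.y[jj], pair.z_tibia[ii, jj]]
    )
    directions = pair.normals_tibia[ii, jj]

    zf = _femur_interp(pair)

    def gap(points: np.ndarray) -> np.ndarray:
        return zf(points[:, :2]) - points[:, 2]

    hit, length = _march_to_crossing(origins, directions, gap, max_distance, step, bisect=True)
    hit_point = origins + length[:, None] * directions
    hit_point[~hit] = np.nan

    n = origins.shape[0]
    return DistanceSampleSet(
        x=origins[:, 0],
        y=origins[:, 1],
        z=origins[:, 2],
        distance=length,
        hit_point=hit_point,
        hit=hit,
        reflected=np.zeros(n, dtype=bool),
        compartment=np.full(n, "", dtype="<U13"),
        included=np.zeros(n, dtype=bool),
    )


def reflection_filter(
    samples: DistanceSampleSet,
    pair: SurfacePair,
    max_distance: float = 15.0,
    step: float = 0.25,
) -> DistanceSampleSet:
    """Flag samples whose femoral return perpendicular meets the tibia.

    From each femoral hit point a ray is cast along the femoral inward
    (downward) unit normal; the sample is 'reflected' iff that ray
    intersects the defined tibial surface within ``max_distance``.  A pure
    filter: distances are untouched and no samples are added.
    """
    if samples.x.size and pair.x.size:
        # sanity: samples must lie on the pair's grid extent
        if samples.x.min() < pair.x[0] - 1e-6 or samples.x.max() > pair.x[-1] + 1e-6:
            raise ValidationError("sample set does not match the surface pair grid")

    reflected = np.zeros(len(samples), dtype=bool)
    idx = np.nonzero(samples.hit)[0]
    if idx.size:
        hits = samples.hit_point[idx]
        # femoral inward normal at the hit point, interpolated per component
        comps = []
        for c in range(3):
            interp = RegularGridInterpolator(
                (pair.x, pair.y),
                pair.normals_femur[..., c],
                bounds_error=False,
                fill_value=np.nan,
            )
            comps.append(interp(hits[:, :2]))
        directions = np.column_stack(comps)
        valid = ~np.isnan(directions).any(axis=1)
        directions[valid] /= np.linalg.norm(directions[valid], axis=1, keepdims=True)

        zt = _tibia_interp(pair)

        def gap(points: np.ndarray) -> np.ndarray:
            # positive while above the tibial surface
            return points[:, 2] - zt(points[:, :2])

        sub = np.nonzero(valid)[0]
        if sub.size:
            hit_back, _ = _march_to_crossing(
                hits[sub], directions[sub], gap, max_distance, step, bisect=False
            )
            reflected[idx[sub]] = hit_back

    out = DistanceSampleSet(
        x=samples.x,
        y=samples.y,
        z=samples.z,
        distance=samples.distance,
        hit_point=samples.hit_point,
        hit=samples.hit,
        reflected=reflected,
        compartment=samples.compartment,
        included=samples.included,
    )
    return out


def label_compartments(
    samples: DistanceSampleSet,
    regions: CompartmentRegions,
    joint_left_x: float = 0.0,
) -> DistanceSampleSet:
    """Assign region labels and the included flag in place.

    ``joint_left_x`` maps the regions' joint-width coordinates to absolute
    sample x positions (the x of the joint's left outer border).
    """
    rel = samples.x - joint_left_x
    samples.compartment[:] = ""
    for name in ("medial", "lateral"):
        lo, hi = regions.interval(name)
        sel = (rel >= lo) & (rel <= hi)
        samples.compartment[sel] = name
    samples.included[:] = (
        samples.hit & samples.reflected & (samples.compartment != "")
    )
    return samples


def median_jsw(
    samples: DistanceSampleSet,
    regions: CompartmentRegions,
    compartment: str,
    joint_left_x: float = 0.0,
    min_count: int = 10,
) -> JSWResult:
    """Median (and mean) perpendicular JSW over one compartment region.

    Only samples that are hits, pass the reflection filter, and lie inside
    the compartment's region contribute.  Even sample counts use the
    midpoint of the two central values.
    """
    lo, hi = regions.interval(compartment)
    rel = samples.x - joint_left_x
    in_region = (rel >= lo) & (rel <= hi)
    included = in_region & samples.hit & samples.reflected
    n = int(included.sum())
    if n < min_count:
        raise MeasurementError(
            f"only {n} included samples in {compartment} region "
            f"(minimum {min_count})"
        )
    d = samples.distance[included]
    return JSWResult(
        compartment=compartment,
        median_jsw=float(np.median(d)),
        mean_jsw=float(np.mean(d)),
        n_included=n,
        included_area_fraction=float(included.sum() / max(in_region.sum(), 1)),
    )
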