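"""MRI-style mean cartilage thickness of a compartment.

The thickness observable mirrors quantitative MRI cartilage morphometry:
per-point cartilage thickness over the tibial and femoral plates of a
compartment, averaged into a single mean thickness.  Tibial and femoral
values are pooled point-by-point into one average (so with 2 mm cartilage
on each plate the mean thickness is 2 mm and the bone-to-bone distance
roughly twice that); per-plate means are reported alongside.  The
measurement contract is non-weight-bearing: thickness maps must come from
an unloaded joint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import MeasurementError, ValidationError
from .volume import Volume3D

logger = logging.getLogger(__name__)


@dataclass
class ThicknessResult:
    compartment: str
    mean_thickness: float  # mm, pooled over both plates
    tibial_mean: float  # mm
    femoral_mean: float  # mm
    plate_mean_average: float  # mm, average of the two plate means
    n_samples: int


def mean_cartilage_thickness(
    c_tibia: np.ndarray,
    c_femur: np.ndarray,
    compartment_map: np.ndarray,
    compartment: str,
    loaded: bool = False,
) -> ThicknessResult:
    """Mean cartilage thickness of one compartment.

    Pools tibial and femoral per-point thickness values over the
    compartment and averages them; per-plate means and their average are
    also reported (the two aggregations coincide when both plates cover
    the compartment equally).  Raises if the maps come from a loaded
    joint — thickness is a non-weight-bearing measurement.
    """
    if loaded:
        raise ValidationError(
            "cartilage thickness is measured non-weight-bearing; got loaded maps"
        )
    if c_tibia.shape != c_femur.shape or c_tibia.shape != compartment_map.shape:
        raise ValidationError("thickness and compartment maps must share a grid")
    if np.nanmin(c_tibia) < 0 or np.nanmin(c_femur) < 0:
        raise ValidationError("thickness maps must be >= 0")
    sel = compartment_map == compartment
    if not sel.any():
        raise MeasurementError(f"compartment {compartment!r} is empty")
    t_vals = c_tibia[sel]
    f_vals = c_femur[sel]
    t_vals = t_vals[~np.isnan(t_vals)]
    f_vals = f_vals[~np.isnan(f_vals)]
    if t_vals.size == 0 and f_vals.size == 0:
        raise MeasurementError(f"no defined thickness values in {compartment!r}")
    pooled = np.concatenate([t_vals, f_vals])
    t_mean = float(t_vals.mean()) if t_vals.size else float("nan")
    f_mean = float(f_vals.mean()) if f_vals.size else float("nan")
    return ThicknessResult(
        compartment=compartment,
        mean_thickness=float(pooled.mean()),
        tibial_mean=t_mean,
        femoral_mean=f_mean,
        plate_mean_average=float(np.nanmean([t_mean, f_mean])),
        n_samples=int(pooled.size),
    )


def thickness_from_mask(
    cartilage_mask: Volume3D,
    x: np.ndarray,
    y: np.ndarray,
    z_surface: np.ndarray,
    normals: np.ndarray,
    max_thickness: float = 10.0,
    step: float | None = None,
) -> np.ndarray:
    """Normal-direction cartilage thickness from a binary mask.

    For each bone-surface point, a ray is marched along the surface normal
    and the thickness is the length of the contiguous run of mask voxels
    encountered starting at the surface.  Points whose ray never enters
    the mask get zero thickness (with a warning if that holds everywhere).
    """
    if step is None:
        step = min(cartilage_mask.spacing) / 2
    data = cartilage_mask.data.astype(bool)
    spacing = np.array(cartilage_mask.spacing)
    origin = np.array(cartilage_mask.origin)

    defined = ~np.isnan(z_surface)
    ii, jj = np.nonzero(defined)
    origins = np.column_stack([x[ii], y[jj], z_surface[ii, jj]])
    dirs = normals[ii, jj]

    n = origins.shape[0]
    thickness = np.zeros(n)
    entered = np.zeros(n, dtype=bool)
    exited = np.zeros(n, dtype=bool)
    ts = np.arange(0, max_thickness + step, step)
    for t in ts:
        pts = origins + t * dirs
        idx = np.round((pts - origin) / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(data.shape)), axis=1)
        in_mask = np.zeros(n, dtype=bool)
        ic = idx[inside]
        in_mask[inside] = data[ic[:, 0], ic[:, 1], ic[:, 2]]
        newly = in_mask & ~entered
        entered |= newly
        leaving = entered & ~exited & ~in_mask
        # allow a half-voxel tolerance right at the surface before declaring entry
        exited |= leaving & (thickness > 0)
        grow = entered & ~exited & in_mask
        thickness[grow] += step

    if not entered.any():
        logger.warning("cartilage mask not adjacent to the bone surface: zero map")
    full = np.zeros(z_surface.shape)
    full[ii, jj] = thickness
    full[~defined] = np.nan
    return full
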