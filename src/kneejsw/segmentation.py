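"""Bone segmentation of CT-like volumes and opposing-surface extraction.

Segmentation is threshold-based with small-object removal and morphological
closing — the semi-automatic step of the measurement protocol, with an
optional seed-label image taking the place of manual interaction.  Surface
extraction converts the two bone masks into the pair of opposing height
fields (tibial superior, femoral inferior) that the perpendicular JSW
measurement operates on, with sub-voxel refinement by linear interpolation
of the thresholded intensity profile when the source volume is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .errors import SegmentationError, ValidationError
from .volume import Volume3D


@dataclass
class BoneMasks:
    """Disjoint tibia/femur binary masks on the source voxel grid."""

    tibia: np.ndarray
    femur: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.tibia.shape != self.femur.shape:
            raise ValidationError("tibia and femur masks must share a grid")
        if np.any(self.tibia & self.femur):
            raise ValidationError("bone masks overlap")


@dataclass
class SurfacePair:
    """Opposing bone surfaces as height fields on a shared (x, y) grid.

    ``z_tibia`` is the tibial superior surface, ``z_femur`` the femoral
    inferior surface (mm; NaN where the column lacks the bone).  Normals
    are unit vectors; tibial normals point up (+z), femoral normals down.
    """

    x: np.ndarray  # (nx,) mm
    y: np.ndarray  # (ny,) mm
    z_tibia: np.ndarray  # (nx, ny) mm, NaN undefined
    z_femur: np.ndarray  # (nx, ny) mm, NaN undefined
    normals_tibia: np.ndarray  # (nx, ny, 3), unit, nz > 0
    normals_femur: np.ndarray  # (nx, ny, 3), unit, nz < 0
    spacing: tuple[float, float]

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.z_tibia) & ~np.isnan(self.z_femur)


def segment_bones(
    volume: Volume3D,
    threshold: float = 500.0,
    min_component: int = 27,
    closing_radius: int = 1,
    seed_labels: np.ndarray | None = None,
) -> BoneMasks:
    """Segment tibia and femur from a CT-like volume.

    Voxels above ``threshold`` are candidate bone; connected components
    smaller than ``min_component`` voxels are discarded and the two largest
    components kept.  The component with the lower centroid along z is the
    tibia.  ``seed_labels`` (1 = tibia, 2 = femur) overrides the automatic
    tibia/femur assignment where the z-ordering is ambiguous — the stand-in
    for the protocol's manual interaction.
    """
    binary = volume.data > threshold
    binary = morphology.remove_small_objects(binary, max_size=min_component - 1)
    labels = measure.label(binary)
    props = measure.regionprops(labels)
    if len(props) < 2:
        raise SegmentationError(
            f"expected >= 2 bone components above threshold {threshold}, "
            f"found {len(props)}"
        )
    props.sort(key=lambda p: p.area, reverse=True)
    a, b = props[0], props[1]

    if seed_labels is not None:
        tib_lab = _majority_label(labels, seed_labels == 1, (a.label, b.label))
        fem_lab = _majority_label(labels, seed_labels == 2, (a.label, b.label))
        if tib_lab is None or fem_lab is None or tib_lab == fem_lab:
            raise SegmentationError("seed labels do not select two distinct components")
    else:
        za, zb = a.centroid[2], b.centroid[2]
        if abs(za - zb) < 1.0:  # centroids within one voxel along z
            raise SegmentationError(
                "tibia/femur z-ordering ambiguous; supply seed_labels "
                "(1 = tibia, 2 = femur)"
            )
        (tib_lab, fem_lab) = (a.label, b.label) if za < zb else (b.label, a.label)

    tibia = labels == tib_lab
    femur = labels == fem_lab
    if closing_radius > 0:
        ball = morphology.ball(closing_radius)
        tibia = morphology.closing(tibia, ball).astype(bool)
        femur = morphology.closing(femur, ball).astype(bool)
        femur &= ~tibia  # closing must not create overlap
    return BoneMasks(tibia, femur, volume.spacing, volume.origin)


def _majority_label(labels: np.ndarray, seed: np.ndarray, allowed: tuple) -> int | None:
    hits = labels[seed]
    hits = hits[np.isin(hits, allowed)]
    if hits.size == 0:
        return None
    vals, counts = np.unique(hits, return_counts=True)
    return int(vals[np.argmax(counts)])


def extract_surfaces(
    masks: BoneMasks,
    volume: Volume3D | None = None,
    threshold: float = 500.0,
) -> SurfacePair:
    """Extract the tibial superior and femoral inferior height fields.

    Per (x, y) column, the tibial surface is the top of the highest tibia
    voxel and the femoral surface the bottom of the lowest femur voxel
    (first bone crossing; internal cavities ignored).  When the source
    ``volume`` is given, the surface position is refined to sub-voxel
    precision by linearly interpolating the intensity profile across
    ``threshold``.  Columns lacking either bone are NaN.  Normals follow
    from central differences of the height fields.
    """
    sx, sy, sz = masks.spacing
    nx, ny, nz = masks.tibia.shape
    z0 = masks.origin[2]

    z_t = _surface_z(masks.tibia, top=True, z0=z0, sz=sz)
    z_f = _surface_z(masks.femur, top=False, z0=z0, sz=sz)

    if volume is not None:
        z_t = _refine_subvoxel(z_t, volume, threshold, rising=False)
        z_f = _refine_subvoxel(z_f, volume, threshold, rising=True)

    x = masks.origin[0] + np.arange(nx) * sx
    y = masks.origin[1] + np.arange(ny) * sy
    n_t = surface_normals(x, y, z_t, upward=True)
    n_f = surface_normals(x, y, z_f, upward=False)
    return SurfacePair(x, y, z_t, z_f, n_t, n_f, (sx, sy))


def _surface_z(mask: np.ndarray, top: bool, z0: float, sz: float) -> np.ndarray:
    """Height field of the top (or bottom) bone voxel boundary per column."""
    nz = mask.shape[2]
    any_bone = mask.any(axis=2)
    if top:
        idx = nz - 1 - np.argmax(mask[:, :, ::-1], axis=2)
        z = z0 + idx * sz + sz / 2  # upper voxel boundary
    else:
        idx = np.argmax(mask, axis=2)
        z = z0 + idx * sz - sz / 2  # lower voxel boundary
    return np.where(any_bone, z, np.nan)


def _refine_subvoxel(
    z: np.ndarray, volume: Volume3D, threshold: float, rising: bool
) -> np.ndarray:
    """Refine a height field by interpolating the intensity threshold crossing.

    ``rising=False``: intensity falls with z across the surface (top of
    tibia); ``rising=True``: intensity rises with z (bottom of femur).
    """
    sz = volume.spacing[2]
    z0 = volume.origin[2]
    nz = volume.data.shape[2]
    out = z.copy()
    defined = ~np.isnan(z)
    # z sits on a voxel boundary: recover the bone-side voxel centre index,
    # then bracket the crossing with the adjacent gap-side voxel.
    if rising:  # femoral inferior surface: bone above, gap below
        k_b = np.round((z[defined] - z0) / sz + 0.5).astype(int)
        k_g = k_b - 1
    else:  # tibial superior surface: bone below, gap above
        k_b = np.round((z[defined] - z0) / sz - 0.5).astype(int)
        k_g = k_b + 1
    k_b = np.clip(k_b, 0, nz - 1)
    k_g = np.clip(k_g, 0, nz - 1)
    ii, jj = np.nonzero(defined)
    i_b = volume.data[ii, jj, k_b]
    i_g = volume.data[ii, jj, k_g]
    denom = i_b - i_g
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(np.abs(denom) > 1e-12, (i_b - threshold) / denom, 0.5)
    frac = np.clip(frac, 0.0, 1.0)
    z_b = z0 + k_b * sz
    z_g = z0 + k_g * sz
    out[ii, jj] = z_b + frac * (z_g - z_b)
    return out


def surface_normals(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, upward: bool
) -> np.ndarray:
    """Unit normals of a height field from central-difference gradients."""
    with np.errstate(invalid="ignore"):
        gx, gy = np.gradient(z, x, y)
    sign = 1.0 if upward else -1.0
    n = np.stack([-sign * gx, -sign * gy, np.full_like(z, sign)], axis=-1)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    return n / norm


def surfaces_from_phantom(phantom) -> SurfacePair:
    """Build a SurfacePair directly from a phantom's analytic height fields.

    This is the fast measurement path: the same surface representation the
    imaging pipeline produces, without rendering and re-segmenting a volume.
    """
    x, y = phantom.x, phantom.y
    n_t = surface_normals(x, y, phantom.z_tibia, upward=True)
    n_f = surface_normals(x, y, phantom.z_femur, upward=False)
    return SurfacePair(
        x,
        y,
        phantom.z_tibia.copy(),
        phantom.z_femur.copy(),
        n_t,
        n_f,
        (float(x[1] - x[0]), float(y[1] - y[0])),
    )
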