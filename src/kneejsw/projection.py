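"""Standardized pose and coronal over-projection (pseudo-radiograph).

To mimic the acquisition geometry of a standardized posteroanterior knee
radiograph, the volume is first brought to a standard pose: the tibial
plateau is made parallel to the axial plane (least-squares plane fit to
the tibial superior surface) and the line through the posterior-most
points of the two femoral condyles is made parallel to the coronal plane.
The tibia-femur relative pose is never changed — one rigid transform is
applied to the whole volume.  The repositioned volume is then collapsed
along the anteroposterior axis into a 2D over-projection, and a step
wedge of known physical step length is embedded so the pixel size can be
recovered from the image alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import MeasurementError, ValidationError
from .segmentation import BoneMasks, extract_surfaces
from .volume import Volume3D


@dataclass
class RigidPose:
    """Rigid transform p -> R @ p + t (mm), with fitting provenance."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValidationError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "rotation": self.rotation.tolist(),
                    "translation": self.translation.tolist(),
                    "provenance": {
                        k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in self.provenance.items()
                    },
                },
                indent=2,
            )
        )


@dataclass
class WedgeDescriptor:
    """Where the calibration wedge sits and what it encodes."""

    row_start: int
    row_stop: int
    col_start: int
    steps: int
    step_length_mm: float
    intensities: list[float]


@dataclass
class Projection2D:
    """Coronal over-projection: rows along -z (row 0 superior), cols along x."""

    image: np.ndarray  # (n_rows, n_cols) intensities
    pixel_size: float  # mm per pixel (isotropic in the image plane)
    wedge: WedgeDescriptor | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel size must be > 0")

    def save_png(self, path: str | Path) -> None:
        import imageio.v3 as iio

        img = np.clip(self.image, 0, 65535).astype(np.uint16)
        iio.imwrite(str(path), img)
        side = Path(str(path) + ".json")
        payload = {"pixel_size": self.pixel_size, "meta": self.meta}
        if self.wedge is not None:
            payload["wedge"] = self.wedge.__dict__
        side.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load_png(cls, path: str | Path) -> "Projection2D":
        import imageio.v3 as iio

        img = np.asarray(iio.imread(str(path)), dtype=float)
        side = Path(str(path) + ".json")
        pixel_size, wedge, meta = 1.0, None, {}
        if side.exists():
            payload = json.loads(side.read_text())
            pixel_size = payload.get("pixel_size", 1.0)
            meta = payload.get("meta", {})
            if "wedge" in payload:
                wedge = WedgeDescriptor(**payload["wedge"])
        return cls(img, pixel_size, wedge, meta)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1 / (1 + c))


def standardize_pose(masks: BoneMasks, distal_fraction: float = 0.4) -> RigidPose:
    """Fit the standard radiographic pose from the bone masks.

    Rotation 1 aligns the least-squares tibial plateau plane normal with
    +z; rotation 2 (about z) aligns the posterior condylar line — through
    the posterior-most femoral point of each mediolateral half, searched in
    the distal ``distal_fraction`` of the femur — with the x-axis.  The
    transform rotates about the tibial surface centroid, which stays fixed.
    """
    pair = extract_surfaces(masks)
    defined_t = ~np.isnan(pair.z_tibia)
    if defined_t.sum() < 3:
        raise MeasurementError("too few tibial surface points to fit a plane")
    ii, jj = np.nonzero(defined_t)
    pts_t = np.column_stack([pair.x[ii], pair.y[jj], pair.z_tibia[ii, jj]])

    # least-squares plane z = ax + by + c
    A = np.column_stack([pts_t[:, 0], pts_t[:, 1], np.ones(len(pts_t))])
    coef, *_ = np.linalg.lstsq(A, pts_t[:, 2], rcond=None)
    a, b, c = coef
    normal = np.array([-a, -b, 1.0])
    normal /= np.linalg.norm(normal)
    r1 = _rotation_between(normal, np.array([0.0, 0.0, 1.0]))

    centroid = pts_t.mean(axis=0)

    # femoral inferior surface points; level them with rotation 1 first,
    # then keep the distal part only (avoid shaft and rim interference)
    defined_f = ~np.isnan(pair.z_femur)
    fi, fj = np.nonzero(defined_f)
    pts_f = np.column_stack([pair.x[fi], pair.y[fj], pair.z_femur[fi, fj]])
    level = (pts_f - centroid) @ r1.T + centroid
    z_lo, z_hi = level[:, 2].min(), level[:, 2].max()
    rot1 = level[level[:, 2] <= z_lo + distal_fraction * max(z_hi - z_lo, 1e-9)]
    if len(rot1) < 2:
        raise MeasurementError("too few distal femoral points for condylar landmarks")

    x_mid = np.median(rot1[:, 0])
    left = rot1[rot1[:, 0] <= x_mid]
    right = rot1[rot1[:, 0] > x_mid]
    if len(left) == 0 or len(right) == 0:
        raise MeasurementError(
            "condyles indistinguishable (single posterior extremum); "
            "supply manual landmarks"
        )
    p_left = left[np.argmin(left[:, 1])]
    p_right = right[np.argmin(right[:, 1])]
    d = p_right - p_left
    theta = float(np.arctan2(d[1], d[0]))  # angle of condylar line vs x-axis
    cz, sz_ = np.cos(-theta), np.sin(-theta)
    r2 = np.array([[cz, -sz_, 0.0], [sz_, cz, 0.0], [0.0, 0.0, 1.0]])

    rotation = r2 @ r1
    translation = centroid - rotation @ centroid
    return RigidPose(
        rotation,
        translation,
        provenance={
            "plateau_plane": [float(a), float(b), float(c)],
            "condyle_left": p_left,
            "condyle_right": p_right,
            "condylar_angle_rad": theta,
        },
    )


def resample_volume(volume: Volume3D, pose: RigidPose, order: int = 1) -> Volume3D:
    """Resample a volume under a rigid pose (trilinear by default).

    The output grid equals the input grid; each output voxel looks up the
    input at the inverse-transformed physical position.
    """
    spacing = np.array(volume.spacing)
    origin = np.array(volume.origin)
    r_inv = pose.rotation.T
    # index_in = (R^-1 ((idx_out * s + o) - t) - o) / s
    matrix = (r_inv * spacing[None, :]) / spacing[:, None]
    offset = (r_inv @ (origin - pose.translation) - origin) / spacing
    data = ndimage.affine_transform(
        volume.data, matrix, offset=offset, order=order, mode="constant", cval=0.0
    )
    return Volume3D(data, volume.spacing, volume.origin, dict(volume.meta))


def project_coronal(
    volume: Volume3D, pose: RigidPose | None = None, mode: str = "max"
) -> Projection2D:
    """Collapse the (repositioned) volume along the anteroposterior axis.

    ``max`` (default) gives the bone silhouette — the radiographic
    behaviour for bright bone on a radiolucent background; ``sum`` mimics
    accumulated attenuation.  Row 0 of the image is the superior edge.
    """
    if mode not in ("max", "sum"):
        raise ValidationError(f"unknown projection mode {mode!r}")
    vol = volume if pose is None else resample_volume(volume, pose)
    collapsed = vol.data.max(axis=1) if mode == "max" else vol.data.sum(axis=1)
    image = collapsed.T[::-1].copy()  # (rows=z top-down, cols=x)
    sx, _, sz = vol.spacing
    if abs(sx - sz) > 1e-6 * max(sx, sz):
        raise ValidationError(
            f"anisotropic in-plane spacing ({sx} x {sz} mm): resample first"
        )
    return Projection2D(
        image,
        pixel_size=float(sx),
        meta={"mode": mode, "origin_x": vol.origin[0], "origin_z": vol.origin[2]},
    )


def embed_wedge(
    proj: Projection2D,
    pixel_size: float | None = None,
    steps: int = 5,
    step_length_mm: float = 10.0,
    wedge_rows: int = 8,
    base_intensity: float = 200.0,
    add_margin: bool = True,
) -> Projection2D:
    """Embed a calibration step wedge in the bottom margin of the image.

    Each step spans a fixed physical length (default 10 mm), so the step
    length in pixels encodes the pixel size.  Step intensities increase
    strictly.  With ``add_margin`` (default) an empty margin of
    ``wedge_rows`` rows is appended below the image; otherwise the
    existing bottom rows must be empty (all below ``base_intensity``).
    """
    if steps <= 0:
        raise ValidationError(f"wedge needs >= 1 step, got {steps}")
    if pixel_size is None:
        pixel_size = proj.pixel_size
    step_px = int(round(step_length_mm / pixel_size))
    if step_px < 2:
        raise ValidationError("pixel size too coarse for the wedge step length")
    total_px = steps * step_px
    n_rows, n_cols = proj.image.shape
    if total_px > n_cols:
        raise ValidationError(
            f"image too narrow for wedge: need {total_px} px, have {n_cols}"
        )
    if add_margin:
        image = np.vstack([proj.image, np.zeros((wedge_rows, n_cols))])
        n_rows += wedge_rows
    else:
        if wedge_rows >= n_rows:
            raise ValidationError("image too short for wedge margin")
        margin = proj.image[n_rows - wedge_rows :, :total_px]
        if np.any(margin >= base_intensity):
            raise ValidationError("bottom margin not empty; cannot embed wedge")
        image = proj.image.copy()
    intensities = [base_intensity * (i + 1) for i in range(steps)]
    for i, val in enumerate(intensities):
        image[n_rows - wedge_rows :, i * step_px : (i + 1) * step_px] = val
    wedge = WedgeDescriptor(
        row_start=n_rows - wedge_rows,
        row_stop=n_rows,
        col_start=0,
        steps=steps,
        step_length_mm=step_length_mm,
        intensities=intensities,
    )
    return Projection2D(image, proj.pixel_size, wedge, dict(proj.meta))
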