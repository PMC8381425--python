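"""A minimal 3D intensity volume with physical spacing.

Axis convention used throughout the package: array index order is
``(ix, iy, iz)`` for the (x = mediolateral, y = anteroposterior,
z = inferosuperior) axes, with physical coordinate of a voxel centre
``origin + index * spacing`` per axis, in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError


@dataclass
class Volume3D:
    """Intensity volume with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"voxel spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def coords(self, axis: int) -> np.ndarray:
        """Physical centre coordinates (mm) of voxels along ``axis``."""
        return self.origin[axis] + np.arange(self.data.shape[axis]) * self.spacing[axis]

    def save(self, path: str | Path) -> None:
        """Write to NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) by extension."""
        path = Path(path)
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            affine = np.diag(list(self.spacing) + [1.0])
            affine[:3, 3] = self.origin
            nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), str(path))
        elif name.endswith((".mha", ".mhd")):
            import SimpleITK as sitk

            # SimpleITK indexes (z, y, x); transpose our (x, y, z) array.
            img = sitk.GetImageFromArray(np.asarray(self.data, dtype=np.float32).transpose(2, 1, 0))
            img.SetSpacing(self.spacing)
            img.SetOrigin(self.origin)
            sitk.WriteImage(img, str(path))
        else:
            raise ValidationError(f"unsupported volume format: {path.name}")

    @classmethod
    def load(cls, path: str | Path) -> "Volume3D":
        path = Path(path)
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(str(path))
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            origin = tuple(float(v) for v in img.affine[:3, 3])
            return cls(np.asarray(img.dataobj), spacing, origin)
        if name.endswith((".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
            return cls(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
        raise ValidationError(f"unsupported volume format: {path.name}")
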