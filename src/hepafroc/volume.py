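"""3D volume container with voxel spacing and optional liver mask.

Array axes are (x, y, z); world coordinates are ``index * spacing`` in mm.
NIfTI I/O carries the spacing on the affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import ValidationError


@dataclass
class Volume:
    data: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValidationError("volume data must be 3D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive values (mm)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValidationError("mask shape must equal data shape")

    @property
    def shape(self):
        return self.data.shape

    def world_to_voxel(self, pos_mm) -> np.ndarray:
        return np.asarray(pos_mm, dtype=float) / np.asarray(self.spacing)

    def voxel_to_world(self, idx) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing)


def save_nifti(volume: Volume, path) -> None:
    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))
    if volume.mask is not None:
        raise ValidationError("save the mask separately with save_nifti_mask")


def save_nifti_mask(volume: Volume, path) -> None:
    if volume.mask is None:
        raise ValidationError("volume carries no mask")
    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(volume.mask.astype(np.uint8), affine), str(path))


def load_nifti(path, mask_path=None) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return Volume(np.asarray(img.dataobj, dtype=np.float32), spacing, mask)
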