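"""Minimal 3-D image and mask containers with physical spacing.

Volumes are stored as plain ``numpy`` arrays in index order ``(x, y, z)``
with isotropic-or-not voxel spacing in millimetres and a world origin.
NIfTI-1 round-tripping goes through :mod:`nibabel` with an RAS+ affine
built from spacing and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Image3D", "Mask3D"]


def _as_spacing(spacing) -> np.ndarray:
    s = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError(f"spacing must be positive and finite, got {s}")
    return s


@dataclass
class Image3D:
    """A 3-D intensity volume (activity-like units, non-negative by convention).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities.
    spacing : float or sequence of 3 floats
        Voxel edge lengths in mm.
    origin : sequence of 3 floats, optional
        World coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Image3D requires a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Image3D values must be finite")
        self.spacing = _as_spacing(self.spacing)
        self.origin = np.broadcast_to(np.asarray(self.origin, dtype=float), (3,)).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine()), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Image3D":
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj, dtype=float)
        aff = img.affine
        spacing = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
        return cls(arr, spacing, aff[:3, 3])


@dataclass
class Mask3D:
    """A binary lesion mask on the same grid as its paired image."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("Mask3D requires a 3-D array")
        if not self.values.any():
            raise ValueError("Mask3D must contain at least one foreground voxel")
        self.spacing = _as_spacing(self.spacing)
        self.origin = np.broadcast_to(np.asarray(self.origin, dtype=float), (3,)).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def check_compatible(self, image: Image3D) -> None:
        if self.values.shape != image.values.shape:
            raise ValueError("mask and image grids differ in shape")
        if not np.allclose(self.spacing, image.spacing):
            raise ValueError("mask and image grids differ in spacing")

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), self.affine()), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Mask3D":
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        aff = img.affine
        spacing = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
        return cls(arr > 0.5, spacing, aff[:3, 3])
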