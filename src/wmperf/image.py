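"""Minimal 3-D image container used throughout the pipeline.

All stages exchange :class:`ImageVolume` objects: a scalar field on a regular
voxel grid together with the physical voxel sizes.  Persistence is NIfTI-1
via nibabel, with a diagonal affine built from the voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class ImageVolume:
    """A 3-D scalar field with per-axis voxel sizes in millimetres."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires 3-D data, got shape {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def check_grid(self, other: "ImageVolume", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grid {other.shape}@{other.voxel_size_mm} does not match "
                f"{self.shape}@{self.voxel_size_mm}"
            )

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(np.asarray(data), self.voxel_size_mm)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.dataobj, dtype=np.float64), tuple(float(z) for z in zooms))


def save_4d(volumes: np.ndarray, voxel_size_mm, path) -> None:
    """Write a (x, y, z, t) array as a 4-D NIfTI-1 image."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volumes, dtype=np.float64), affine), str(path))


def load_4d(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj, dtype=np.float64), tuple(float(z) for z in zooms)
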