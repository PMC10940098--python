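"""3D image volumes and binary voxel masks with physical spacing.

Arrays are indexed ``(z, y, x)``; ``spacing`` is millimetres per voxel along
the same axis order.  Masks are inclusive voxel sets (no partial volumes) and
voxel positions refer to voxel centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "VoxelMask", "RegionPair", "load_nifti_volume",
           "load_nifti_mask"]


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be three positive reals, got {spacing}")
    return s


@dataclass
class ImageVolume:
    """Real-valued 3D grid with physical voxel spacing (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def save(self, path: str | Path) -> None:
        _save_nifti(self.values.astype(np.float32), self.spacing, path)


@dataclass
class VoxelMask:
    """Binary 3D grid sharing the geometry conventions of ImageVolume."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("mask must be a non-empty 3D grid")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not self.values.any()

    def coordinates_mm(self) -> np.ndarray:
        """Physical (z, y, x) coordinates of foreground voxel centres, (n, 3)."""
        idx = np.argwhere(self.values).astype(float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def save(self, path: str | Path) -> None:
        _save_nifti(self.values.astype(np.uint8), self.spacing, path)


@dataclass
class RegionPair:
    """Intratumoral region plus the peritumoral band around the tumor surface."""

    intratumoral: VoxelMask
    peritumoral: VoxelMask
    peritumoral_empty: bool = False
    intratumoral_mode: str = "full"
    notes: list[str] = field(default_factory=list)


def _save_nifti(arr: np.ndarray, spacing, path) -> None:
    # nibabel stores (x, y, z); our arrays are (z, y, x)
    affine = np.diag(list(spacing[::-1]) + [1.0])
    nib.save(nib.Nifti1Image(np.ascontiguousarray(arr.T), affine), str(path))


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).T  # back to (z, y, x)
    zooms = img.header.get_zooms()[:3][::-1]
    return data, tuple(float(z) for z in zooms)


def load_nifti_volume(path: str | Path) -> ImageVolume:
    data, spacing = _load_nifti(path)
    return ImageVolume(data.astype(float), spacing)


def load_nifti_mask(path: str | Path) -> VoxelMask:
    data, spacing = _load_nifti(path)
    return VoxelMask(data > 0.5, spacing)
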