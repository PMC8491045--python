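"""Image-grid containers: intensity volumes and binary segmentation masks.

All geometry lives in physical millimetres on a fixed axis convention:
array axes are ordered (x, y, z) with +x = subject left, +y = posterior,
+z = superior. A voxel at index (i, j, k) has its centre at
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["IntensityVolume", "SegmentationMask"]


def _check_grid(data: np.ndarray, spacing, origin) -> tuple[np.ndarray, np.ndarray]:
    if data.ndim != 3 or data.size == 0:
        raise ValueError("volume grid must be a non-empty 3D array")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing and origin must be length-3 vectors")
    if not np.all(spacing > 0):
        raise ValueError("voxel spacing must be positive on all axes")
    return spacing, origin


@dataclass
class IntensityVolume:
    """A 3D scalar grid of gray-level intensities with physical spacing."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm coordinates."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map mm coordinates to fractional voxel indices."""
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def affine(self) -> np.ndarray:
        aff = np.diag(np.append(self.spacing, 1.0))
        aff[:3, 3] = self.origin
        return aff

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "IntensityVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        origin = aff[:3, 3]
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


@dataclass
class SegmentationMask:
    """A 3D boolean grid on the same lattice as its source volume."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        """Total foreground volume = voxel count x voxel volume."""
        return float(self.data.sum()) * self.voxel_volume

    index_to_physical = IntensityVolume.index_to_physical
    physical_to_index = IntensityVolume.physical_to_index
    affine = IntensityVolume.affine

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine())
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "SegmentationMask":
        img = nib.load(str(path))
        aff = img.affine
        return cls(np.asarray(img.dataobj) > 0, np.abs(np.diag(aff)[:3]), aff[:3, 3])
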