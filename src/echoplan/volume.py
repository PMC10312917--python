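"""Voxel grids and volumes with physical spacing.

Conventions used throughout the package: volume axes are (x, y, z), voxel
indices are 0-based, and the physical position of a voxel *center* is
``origin + index * spacing``.  All distances are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Grid", "VoxelVolume", "SkullMask"]


@dataclass(frozen=True)
class Grid:
    """A regular 3D voxel lattice (no data)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def meshgrid(self) -> list[np.ndarray]:
        """Broadcastable voxel-center coordinate arrays for all three axes."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij", sparse=True)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (mm) spanned by the voxel lattice, edge to edge."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center(self) -> np.ndarray:
        """Physical center of the lattice (mm)."""
        return np.asarray(self.origin) + np.asarray(self.spacing) * (np.asarray(self.shape) - 1) / 2.0


@dataclass
class VoxelVolume:
    """A scalar 3D field (HU, pressure, intensity ...) on a regular grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices (..., 3) to physical mm coordinates."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def mm_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map physical mm coordinates (..., 3) to fractional voxel indices."""
        return (np.asarray(pts, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def save(self, path) -> None:
        """Write as NIfTI-1; spacing goes into the affine diagonal, origin into the translation."""
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        nib.save(nib.Nifti1Image(data, affine), str(path))

    @classmethod
    def load(cls, path) -> "VoxelVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return cls(np.asanyarray(img.dataobj), spacing, origin)


class SkullMask(VoxelVolume):
    """Binary skull occupancy volume."""

    def __post_init__(self):
        super().__post_init__()
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("skull mask must be binary")
            self.data = self.data.astype(bool)

    @classmethod
    def load(cls, path) -> "SkullMask":
        vol = VoxelVolume.load(path)
        return cls(vol.data.astype(bool), vol.spacing, vol.origin)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())
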