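"""Core image containers: sampling grid and SUV volumes.

All volumes in this package live on a regular 3-D grid with a voxel-center
coordinate convention: the world position of voxel ``(i, j, k)`` is
``origin_mm + (index + 0.5) * spacing_mm``.  SUV volumes carry values in
g/mL (body-mass normalised standardized uptake values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["GridSpec", "SuvImage", "load_suv_nifti", "save_suv_nifti"]


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    """Accept a scalar (isotropic) or a length-3 spacing and return a triple."""
    arr = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError("spacing_mm must be a scalar or a length-3 sequence")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("spacing_mm must be positive and finite")
    return tuple(float(s) for s in arr)


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D sampling grid.

    Parameters
    ----------
    shape:
        Voxels per axis, e.g. ``(96, 96, 64)``.
    spacing_mm:
        Voxel edge length in mm.  A scalar means isotropic spacing; the
        default 4.0 mm is the spacing at which a 3x3x3-voxel block occupies
        1.728 mL, the evaluability threshold used throughout.
    origin_mm:
        World coordinate of the grid corner (not the first voxel center).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError("shape must be three positive integers")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", _as_spacing(self.spacing_mm))
        origin = tuple(float(x) for x in self.origin_mm)
        if len(origin) != 3:
            raise ValueError("origin_mm must have three components")
        object.__setattr__(self, "origin_mm", origin)

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float)

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float)

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def isotropic(self) -> bool:
        s = self.spacing
        return bool(np.all(s == s[0]))

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def index_to_world(self, index) -> np.ndarray:
        """World position of a (possibly fractional) voxel index."""
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.spacing

    def world_to_index(self, pos_mm) -> np.ndarray:
        """Fractional voxel index of a world position (inverse of index_to_world)."""
        return (np.asarray(pos_mm, dtype=float) - self.origin) / self.spacing - 0.5

    def contains_index(self, index) -> bool:
        idx = np.asarray(index)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))

    @property
    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Low and high world corners of the grid box."""
        low = self.origin
        high = self.origin + np.asarray(self.shape) * self.spacing
        return low, high

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel index to the voxel-center world position."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin + 0.5 * self.spacing
        return aff


@dataclass
class SuvImage:
    """3-D scalar volume of standardized uptake values (g/mL)."""

    values: np.ndarray
    grid: GridSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SUV volume must be 3-D")
        if self.grid is None:
            self.grid = GridSpec(shape=self.values.shape)
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"volume shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def with_values(self, values: np.ndarray) -> "SuvImage":
        """New image on the same grid."""
        return SuvImage(values=values, grid=self.grid)


def save_suv_nifti(image: SuvImage, path, description: str = "") -> None:
    """Write an SUV volume as NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(image.values.astype(np.float32), image.grid.affine())
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_suv_nifti(path) -> SuvImage:
    """Read an SUV volume written by :func:`save_suv_nifti`.

    The grid is reconstructed from the affine assuming axis-aligned voxels.
    """
    img = nib.load(str(Path(path)))
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3] - 0.5 * spacing
    data = np.asarray(img.dataobj, dtype=float)
    grid = GridSpec(shape=data.shape, spacing_mm=tuple(spacing), origin_mm=tuple(origin))
    return SuvImage(values=np.clip(data, 0.0, None), grid=grid)


def save_mask_nifti(mask: np.ndarray, grid: GridSpec, path) -> None:
    """Write a boolean lesion mask as an unsigned-8-bit NIfTI-1 volume."""
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine())
    nib.save(img, str(path))


def load_mask_nifti(path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(Path(path)))
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3] - 0.5 * spacing
    data = np.asarray(img.dataobj)
    grid = GridSpec(shape=data.shape, spacing_mm=tuple(spacing), origin_mm=tuple(origin))
    return data > 0, grid
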