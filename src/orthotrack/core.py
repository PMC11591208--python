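"""Shared geometric data model and image I/O.

Conventions used throughout the package:

* Voxel indices are 0-based and arrays are indexed ``values[ix, iy, iz]``.
* World axes are fixed as x = LR (left-right), y = AP (anterior-posterior),
  z = SI (superior-inferior); all world units are millimetres.
* Grids are axis-aligned (identity direction matrix); the world position of
  voxel ``(i, j, k)`` is ``origin + index * spacing`` per axis.
* The isocenter is the world position of the grid center and is the origin
  of all :class:`TumorState` coordinates.
* Displacement fields are in mm and use the pull-back convention:
  ``warped(x) = source(x + phi(x))`` for every world point ``x``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "Grid3D",
    "Volume3D",
    "Mask3D",
    "DVF3D",
    "TumorState",
    "voxel_to_world",
    "world_to_voxel",
    "read_volume",
    "write_volume",
    "resample_volume",
]


@dataclass(frozen=True)
class Grid3D:
    """A regular, axis-aligned 3D sampling grid.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts per axis (x, y, z); each >= 1.
    spacing : tuple of float
        Voxel size in mm per axis; each > 0.
    origin : tuple of float
        World position in mm of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid3D is strictly three-dimensional")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape values must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing values must be > 0, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def isocenter(self) -> np.ndarray:
        """World position (mm) of the grid center."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.spacing
        )

    @property
    def extent(self) -> np.ndarray:
        """Physical edge length of the grid per axis in mm (shape * spacing)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def world_grid(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of world coordinates of every voxel."""
        ax = self.world_axes()
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        return np.stack([xs, ys, zs], axis=-1)

    @staticmethod
    def centered(shape: Sequence[int], spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> "Grid3D":
        """A grid whose center (isocenter) sits at world (0, 0, 0)."""
        shape = tuple(int(s) for s in shape)
        spacing = tuple(float(s) for s in spacing)
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
        return Grid3D(shape=shape, spacing=spacing, origin=origin)


def _check_values(grid: Grid3D, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"{name} shape {values.shape} does not match grid {grid.shape}")
    return values


@dataclass
class Volume3D:
    """A scalar intensity field on a :class:`Grid3D` (CT-like units)."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "values").astype(
            np.float32, copy=False
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")


@dataclass
class Mask3D:
    """A binary label field on a :class:`Grid3D` (values in {0, 1})."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        values = _check_values(self.grid, self.values, "values")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary {0, 1}")
        self.values = values.astype(np.uint8, copy=False)

    def center_of_mass(self) -> np.ndarray:
        """World-mm centroid of the foreground, relative to the grid frame."""
        if not self.values.any():
            raise ValueError("center of mass of an empty mask is undefined")
        idx = np.asarray(ndimage.center_of_mass(self.values), dtype=float)
        return voxel_to_world(idx, self.grid)


@dataclass
class DVF3D:
    """A dense displacement field: mm vectors (x, y, z) per voxel."""

    grid: Grid3D
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError(
                f"vector array shape {self.vectors.shape} must be grid shape + (3,)"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite components")

    @staticmethod
    def zeros(grid: Grid3D) -> "DVF3D":
        return DVF3D(grid, np.zeros(grid.shape + (3,), dtype=np.float32))


@dataclass(frozen=True)
class TumorState:
    """A 3D tumor centroid in mm relative to the isocenter (x=LR, y=AP, z=SI)."""

    x_lr: float
    y_ap: float
    z_si: float

    def __post_init__(self) -> None:
        arr = np.array([self.x_lr, self.y_ap, self.z_si], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("tumor state coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_lr, self.y_ap, self.z_si], dtype=float)

    @staticmethod
    def from_array(a: Sequence[float]) -> "TumorState":
        a = np.asarray(a, dtype=float)
        return TumorState(float(a[0]), float(a[1]), float(a[2]))


def voxel_to_world(index: Sequence[float], grid: Grid3D) -> np.ndarray:
    """Map (possibly fractional) voxel indices to world mm: origin + index*spacing."""
    return np.asarray(grid.origin) + np.asarray(index, dtype=float) * np.asarray(grid.spacing)


def world_to_voxel(world: Sequence[float], grid: Grid3D) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (fractional indices allowed)."""
    return (np.asarray(world, dtype=float) - np.asarray(grid.origin)) / np.asarray(grid.spacing)


# ---------------------------------------------------------------------------
# I/O  (NIfTI / NRRD via SimpleITK)
# ---------------------------------------------------------------------------


def _grid_from_sitk(img: sitk.Image) -> Grid3D:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            "only axis-aligned images are supported (identity direction matrix)"
        )
    return Grid3D(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def read_volume(path: str | os.PathLike, binary: bool = False) -> Volume3D | Mask3D:
    """Read a 3D NIfTI/NRRD image.

    Grid spacing and origin come from the file header.  With ``binary=True``
    values are thresholded at 0.5 and a :class:`Mask3D` is returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D image, got {img.GetDimension()}D: {path}")
    grid = _grid_from_sitk(img)
    # SimpleITK arrays come out [z, y, x]; transpose to our [x, y, z].
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    if binary:
        return Mask3D(grid, (values > 0.5).astype(np.uint8))
    return Volume3D(grid, values.astype(np.float32))


def write_volume(
    v: Volume3D | Mask3D, path: str | os.PathLike, make_parents: bool = True
) -> None:
    """Write a volume or mask as NIfTI/NRRD (format chosen by extension)."""
    path = Path(path)
    if not path.parent.exists():
        if make_parents:
            path.parent.mkdir(parents=True, exist_ok=True)
        else:
            raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    arr = v.values.transpose(2, 1, 0)
    if isinstance(v, Mask3D):
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in v.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in v.grid.origin))
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_volume(v: Volume3D | Mask3D, target_shape: Sequence[int]) -> Volume3D | Mask3D:
    """Resample to ``target_shape`` voxels, preserving the physical extent.

    Spacing is rescaled so that ``shape * spacing`` is unchanged.  Intensities
    are interpolated trilinearly, masks nearest-neighbour.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s < 1 for s in target_shape):
        raise ValueError(f"target shape must be three values >= 1, got {target_shape}")
    src = v.grid
    if target_shape == src.shape:
        return type(v)(src, v.values.copy())

    new_spacing = tuple(
        src.spacing[a] * src.shape[a] / target_shape[a] for a in range(3)
    )
    # Keep the physical slab [origin - spacing/2, origin + (shape - 1/2)*spacing]
    # fixed; new voxel centers shift by (new - old) spacing / 2 at the edge.
    new_origin = tuple(
        src.origin[a] - src.spacing[a] / 2.0 + new_spacing[a] / 2.0 for a in range(3)
    )
    new_grid = Grid3D(shape=target_shape, spacing=new_spacing, origin=new_origin)

    # Source voxel indices at which the new voxel centers fall.
    coords = [
        (new_origin[a] + np.arange(target_shape[a]) * new_spacing[a] - src.origin[a])
        / src.spacing[a]
        for a in range(3)
    ]
    ix, iy, iz = np.meshgrid(*coords, indexing="ij")
    order = 0 if isinstance(v, Mask3D) else 1
    out = ndimage.map_coordinates(
        v.values.astype(np.float32), [ix, iy, iz], order=order, mode="nearest"
    )
    if isinstance(v, Mask3D):
        return Mask3D(new_grid, (out > 0.5).astype(np.uint8))
    return Volume3D(new_grid, out.astype(np.float32))
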