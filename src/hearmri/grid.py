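"""Cube partitioning and tri-orientation slicing of normalized volumes.

A spatially normalized volume (full grid 157 x 189 x 136, or any scaled-down
grid) is tiled into ``cube_side``-voxel cubes; boundary cubes keep whatever
remainder the grid leaves.  Each cube is then sliced along the three
anatomical orientations to yield stacks of 2D images on which the 2D SIFT
detector operates.

Axis convention (used everywhere in this package): volume axes ``(i, j, k)``
are voxel indices, 0-based.  ``sagittal`` slices fix axis 0, ``coronal``
fix axis 1 and ``axial`` fix axis 2.  A slice is the 2D array over the two
remaining axes in ascending axis order, so pixel ``(row, col)`` of slice
``s`` maps back to a unique voxel via :func:`local_to_global`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np

ORIENTATIONS = ("sagittal", "coronal", "axial")
#: volume axis held fixed by each slicing orientation
ORIENTATION_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


class GeometryError(ValueError):
    """Raised when indices or cubes fall outside the volume."""


@dataclass(frozen=True)
class CubeSpec:
    """One block of the cube partition.

    ``cube_index`` is the block index along each axis, ``origin`` the global
    voxel offset of its first voxel, and ``extent`` its side lengths (equal
    to the cube side except at grid boundaries).
    """

    cube_index: tuple[int, int, int]
    origin: tuple[int, int, int]
    extent: tuple[int, int, int]


@dataclass
class SliceStack:
    """Ordered 2D slices of one cube along one orientation."""

    cube: CubeSpec
    orientation: str
    slices: list[np.ndarray]


def partition_cubes(grid_shape: Sequence[int], cube_side: int = 20) -> list[CubeSpec]:
    """Tile ``grid_shape`` into cubes of side ``cube_side``.

    Boundary cubes only contain the remaining volume, so a 157 x 189 x 136
    grid with side 20 yields 8 x 10 x 7 = 560 cubes.
    """
    grid_shape = tuple(int(d) for d in grid_shape)
    if len(grid_shape) != 3 or any(d <= 0 for d in grid_shape):
        raise ValueError(f"grid_shape must be 3 positive integers, got {grid_shape}")
    if cube_side < 1:
        raise ValueError(f"cube_side must be >= 1, got {cube_side}")
    n_blocks = [-(-d // cube_side) for d in grid_shape]  # ceil division
    cubes = []
    for bi in range(n_blocks[0]):
        for bj in range(n_blocks[1]):
            for bk in range(n_blocks[2]):
                origin = (bi * cube_side, bj * cube_side, bk * cube_side)
                extent = tuple(
                    min(cube_side, grid_shape[a] - origin[a]) for a in range(3)
                )
                cubes.append(CubeSpec((bi, bj, bk), origin, extent))
    return cubes


def _check_cube_in_volume(volume: np.ndarray, cube: CubeSpec) -> None:
    for a in range(3):
        if cube.origin[a] < 0 or cube.origin[a] + cube.extent[a] > volume.shape[a]:
            raise GeometryError(
                f"cube {cube.cube_index} (origin {cube.origin}, extent "
                f"{cube.extent}) exceeds volume shape {volume.shape}"
            )


def slice_cube(volume: np.ndarray, cube: CubeSpec) -> dict[str, SliceStack]:
    """Slice one cube along the three orientations.

    Returns a dict keyed by orientation.  Pixel values are copied from the
    volume without resampling; stack ``orientation`` has ``extent[axis]``
    slices, each of shape given by the two remaining extents.
    """
    _check_cube_in_volume(volume, cube)
    o, e = cube.origin, cube.extent
    block = volume[o[0] : o[0] + e[0], o[1] : o[1] + e[1], o[2] : o[2] + e[2]]
    stacks = {}
    for orient, axis in ORIENTATION_AXIS.items():
        slices = [
            np.ascontiguousarray(np.take(block, s, axis=axis))
            for s in range(e[axis])
        ]
        stacks[orient] = SliceStack(cube=cube, orientation=orient, slices=slices)
    return stacks


def local_to_global(
    cube: CubeSpec,
    orientation: str,
    slice_index: int,
    pixel: Sequence[float],
) -> tuple[float, float, float]:
    """Map a (slice, pixel) position inside a cube back to global voxel coords.

    ``pixel`` is ``(row, col)`` over the two non-fixed axes in ascending
    order; fractional (sub-pixel) positions are allowed.
    """
    axis = ORIENTATION_AXIS[orientation]
    row, col = float(pixel[0]), float(pixel[1])
    if not (0 <= slice_index < cube.extent[axis]):
        raise GeometryError(
            f"slice index {slice_index} out of range for extent {cube.extent} "
            f"orientation {orientation}"
        )
    other = [a for a in range(3) if a != axis]
    for a, v in zip(other, (row, col)):
        if not (0 <= v < cube.extent[a]):
            raise GeometryError(f"pixel {pixel} out of cube extent {cube.extent}")
    local = [0.0, 0.0, 0.0]
    local[axis] = float(slice_index)
    local[other[0]] = row
    local[other[1]] = col
    return tuple(cube.origin[a] + local[a] for a in range(3))


def global_to_local(
    cube: CubeSpec, orientation: str, voxel: Sequence[float]
) -> tuple[int, tuple[float, float]]:
    """Inverse of :func:`local_to_global`: global voxel -> (slice, (row, col))."""
    axis = ORIENTATION_AXIS[orientation]
    local = [float(voxel[a]) - cube.origin[a] for a in range(3)]
    for a in range(3):
        if not (0 <= local[a] < cube.extent[a]):
            raise GeometryError(f"voxel {tuple(voxel)} not inside cube {cube}")
    other = [a for a in range(3) if a != axis]
    return int(local[axis]), (local[other[0]], local[other[1]])


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data as float64 array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def save_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a NIfTI-1 volume (identity affine by default)."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
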