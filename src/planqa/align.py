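"""Isocenter alignment and common-lattice resampling of dose grids.

The comparison lattice is isotropic (default 1.5 mm), covers only the
intersection of the two voxel-center hulls (no extrapolation) and is anchored
so that the reference isocenter falls exactly on a voxel center — the
isocenter dose check then reads a stored value rather than an interpolated
one.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .core import DoseGrid, VoxelGrid, world_to_index

__all__ = [
    "NoOverlapError",
    "align_by_isocenter",
    "resample_to_lattice",
    "resample_pair_to_common",
]


class NoOverlapError(ValueError):
    """The two dose grids share no spatial region."""


def align_by_isocenter(ref: DoseGrid, eval_: DoseGrid) -> DoseGrid:
    """Translate ``eval_`` so that its isocenter coincides with ``ref``'s.

    Values are untouched; only the grid origin moves.  Idempotent.
    """
    shift = ref.isocenter - eval_.isocenter
    grid = dataclasses.replace(eval_.grid, origin=eval_.grid.origin + shift)
    return DoseGrid(grid, ref.isocenter.copy())


def _lattice_points(origin: np.ndarray, spacing: np.ndarray, dims) -> np.ndarray:
    """World coordinates of all lattice voxel centers, shape (n, 3)."""
    axes = [origin[a] + spacing[a] * np.arange(dims[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def resample_to_lattice(
    grid: VoxelGrid,
    origin,
    spacing,
    dims,
    cval: float = 0.0,
) -> VoxelGrid:
    """Trilinearly resample ``grid`` onto an arbitrary axis-aligned lattice.

    Lattice points outside the source voxel-center hull receive ``cval``.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    dims = tuple(int(d) for d in dims)
    pts = _lattice_points(origin, spacing, dims)
    ci = world_to_index(grid, pts)
    src_dims = np.array(grid.dims, dtype=float)
    inside = np.all((ci >= -1e-9) & (ci <= src_dims - 1 + 1e-9), axis=1)
    ci = np.clip(ci, 0.0, src_dims - 1.0)
    vals = ndimage.map_coordinates(
        np.asarray(grid.values, dtype=float), ci.T, order=1, mode="nearest"
    )
    vals[~inside] = cval
    return VoxelGrid(origin, spacing, vals.reshape(dims))


def resample_pair_to_common(
    ref: DoseGrid, eval_: DoseGrid, spacing_mm: float = 1.5
) -> tuple[DoseGrid, DoseGrid]:
    """Interpolate both doses onto one shared isotropic lattice.

    Preconditions: ``eval_`` already isocenter-aligned to ``ref``.  The shared
    lattice covers the intersection of the two voxel-center hulls and is
    anchored on the reference isocenter.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    if not np.allclose(ref.isocenter, eval_.isocenter, atol=1e-6):
        raise ValueError("eval dose must be isocenter-aligned to ref first")
    lo = np.maximum(ref.grid.center_min, eval_.grid.center_min)
    hi = np.minimum(ref.grid.center_max, eval_.grid.center_max)
    if np.any(hi < lo - 1e-9):
        raise NoOverlapError("no overlap between dose grids")
    iso = ref.isocenter
    s = float(spacing_mm)
    kmin = np.ceil((lo - iso) / s - 1e-9).astype(int)
    kmax = np.floor((hi - iso) / s + 1e-9).astype(int)
    if np.any(kmax < kmin):
        raise NoOverlapError("grid overlap too small for requested spacing")
    origin = iso + kmin * s
    dims = tuple(int(d) for d in (kmax - kmin + 1))
    spacing = np.full(3, s)
    ref_grid = resample_to_lattice(ref.grid, origin, spacing, dims)
    eval_grid = resample_to_lattice(eval_.grid, origin, spacing, dims)
    # interpolation of non-negative data can only produce tiny negative noise
    np.clip(ref_grid.values, 0.0, None, out=ref_grid.values)
    np.clip(eval_grid.values, 0.0, None, out=eval_grid.values)
    return DoseGrid(ref_grid, iso.copy()), DoseGrid(eval_grid, iso.copy())
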