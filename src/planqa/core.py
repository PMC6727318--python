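"""Core domain types shared by every pipeline stage.

All geometry lives in a fixed DICOM-style LPS world frame in millimetres.
Grids are axis aligned (no direction cosines); the ``origin`` is the world
coordinate of the *center* of voxel ``(0, 0, 0)`` and the bounding box
extends half a voxel beyond the extreme voxel centers, matching NIfTI /
DICOM sampling semantics.  Point sets and isocenters are always world
coordinates, never indices.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

FRAME = "LPS-mm"

__all__ = [
    "FRAME",
    "OutsideGridError",
    "GeometryError",
    "VoxelGrid",
    "BinaryMask",
    "DoseGrid",
    "FiducialSet",
    "GammaCriteria",
    "QATolerances",
    "GammaResult",
    "world_to_index",
    "index_to_world",
    "sample_trilinear",
]


class OutsideGridError(ValueError):
    """A world point fell outside the grid bounding box."""


class GeometryError(ValueError):
    """Two grids that must share a lattice do not."""


def _vec3(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(-1)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be finite, got {a}")
    return a.copy()


@dataclasses.dataclass
class VoxelGrid:
    """Axis-aligned 3D scalar lattice (HU or Gy) in world millimetres.

    Parameters
    ----------
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    spacing
        Per-axis voxel pitch in mm; strictly positive.
    values
        3D scalar array; ``values.shape`` defines ``dims``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    frame: str = FRAME

    def __post_init__(self) -> None:
        self.origin = _vec3(self.origin, "origin")
        self.spacing = _vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("dims must be strictly positive")
        if self.frame != FRAME:
            raise ValueError(f"unsupported frame {self.frame!r}; only {FRAME!r}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def center_min(self) -> np.ndarray:
        """World coordinate of the first voxel center."""
        return self.origin.copy()

    @property
    def center_max(self) -> np.ndarray:
        """World coordinate of the last voxel center."""
        return self.origin + (np.array(self.dims) - 1) * self.spacing

    @property
    def bbox_min(self) -> np.ndarray:
        return self.origin - 0.5 * self.spacing

    @property
    def bbox_max(self) -> np.ndarray:
        return self.center_max + 0.5 * self.spacing

    def contains(self, p, tol: float = 0.0) -> bool:
        p = _vec3(p, "p")
        return bool(
            np.all(p >= self.bbox_min - tol) and np.all(p <= self.bbox_max + tol)
        )

    def same_lattice(self, other: "VoxelGrid | BinaryMask", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )

    def copy(self) -> "VoxelGrid":
        return dataclasses.replace(self, values=self.values.copy())


@dataclasses.dataclass
class BinaryMask(VoxelGrid):
    """Boolean lattice sharing the geometry of an associated :class:`VoxelGrid`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=bool)

    @classmethod
    def like(cls, grid: VoxelGrid, values: np.ndarray) -> "BinaryMask":
        values = np.asarray(values, dtype=bool)
        if values.shape != grid.dims:
            raise GeometryError("mask values shape does not match grid dims")
        return cls(grid.origin, grid.spacing, values)

    @property
    def count(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass
class DoseGrid:
    """A dose distribution in Gy plus the plan isocenter (world mm)."""

    grid: VoxelGrid
    isocenter: np.ndarray

    def __post_init__(self) -> None:
        self.isocenter = _vec3(self.isocenter, "isocenter")
        if np.any(np.asarray(self.grid.values) < -1e-9):
            raise ValueError("dose values must be non-negative")
        if not self.grid.contains(self.isocenter):
            raise ValueError(
                f"isocenter {self.isocenter} lies outside the grid bounding box "
                f"[{self.grid.bbox_min}, {self.grid.bbox_max}]"
            )

    def copy(self) -> "DoseGrid":
        return DoseGrid(self.grid.copy(), self.isocenter.copy())


_MODALITIES = ("MRI", "CT")


@dataclasses.dataclass
class FiducialSet:
    """Labeled implanted-marker positions (world mm) from one modality."""

    labels: tuple[str, ...]
    points: np.ndarray  # (n, 3)
    modality: str

    def __post_init__(self) -> None:
        self.labels = tuple(str(lab) for lab in self.labels)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        n = self.points.shape[0]
        if n < 3:
            raise ValueError("at least 3 markers required")
        if len(self.labels) != n:
            raise ValueError("labels and points must have equal length")
        if len(set(self.labels)) != n:
            raise ValueError(f"duplicate marker labels in {self.labels}")
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")
        d = np.linalg.norm(self.points[:, None, :] - self.points[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise ValueError("two markers are (near-)coincident")

    def __len__(self) -> int:
        return self.points.shape[0]

    def point(self, label: str) -> np.ndarray:
        return self.points[self.labels.index(label)]


@dataclasses.dataclass
class GammaCriteria:
    """One gamma-evaluation criterion set (dose-difference %, DTA mm).

    ``search_step_mm`` is the sub-voxel search lattice pitch; ``None`` lets the
    engine pick ``min(spacing)/3`` capped at ``dta_mm/2``.
    """

    dose_diff_pct: float
    dta_mm: float
    low_dose_threshold_fraction: float = 0.20
    normalization: str = "global_max_ref"
    search_step_mm: float | None = None

    def __post_init__(self) -> None:
        if self.dose_diff_pct <= 0:
            raise ValueError("dose_diff_pct must be > 0")
        if self.dta_mm <= 0:
            raise ValueError("dta_mm must be > 0")
        if not (0 <= self.low_dose_threshold_fraction < 1):
            raise ValueError("low_dose_threshold_fraction must be in [0, 1)")
        if self.normalization not in ("global_max_ref", "local"):
            raise ValueError("normalization must be 'global_max_ref' or 'local'")
        if self.search_step_mm is not None:
            if self.search_step_mm <= 0:
                raise ValueError("search_step_mm must be > 0")
            if self.search_step_mm > self.dta_mm + 1e-12:
                raise ValueError("search_step_mm must not exceed dta_mm")

    def label(self) -> str:
        return f"{self.dose_diff_pct:g}%/{self.dta_mm:g}mm"


@dataclasses.dataclass
class QATolerances:
    """All numeric acceptance thresholds of the QA procedure."""

    iso_dose_pct: float = 2.0
    gamma_pass_pct: float = 90.0
    fiducial_tol_mm: float = 1.0
    skin_margin_mm: float = 20.0
    resample_mm: float = 1.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")


@dataclasses.dataclass
class GammaResult:
    """Outcome of one gamma evaluation.

    ``gamma_map`` holds NaN at voxels outside the evaluation mask.
    ``pass_rate_pct`` and ``mean_gamma`` are ``None`` when ``n_evaluated == 0``.
    ``edge_limited`` flags evaluated voxels whose search neighborhood was
    truncated by the evaluated grid's edge.
    """

    pass_rate_pct: float | None
    mean_gamma: float | None
    gamma_map: VoxelGrid
    n_evaluated: int
    criteria: GammaCriteria
    edge_limited: BinaryMask | None = None

    def __post_init__(self) -> None:
        if self.n_evaluated > 0:
            if not (0.0 <= self.pass_rate_pct <= 100.0):
                raise ValueError("pass_rate_pct out of [0, 100]")
            if self.mean_gamma < 0:
                raise ValueError("mean_gamma must be >= 0")
        finite = np.isfinite(self.gamma_map.values).sum()
        if int(finite) != self.n_evaluated:
            raise ValueError("n_evaluated must equal the number of unflagged voxels")


# ---------------------------------------------------------------------------
# coordinate transforms and sampling


def world_to_index(grid: VoxelGrid, p) -> np.ndarray:
    """Continuous (fractional) voxel index of world point(s) ``p``.

    Accepts a single 3-vector or an ``(n, 3)`` array.  The result may lie
    outside ``[0, dims-1]``; no bounds check is applied.
    """
    p = np.asarray(p, dtype=float)
    return (p - grid.origin) / grid.spacing


def index_to_world(grid: VoxelGrid, ijk) -> np.ndarray:
    """World coordinates of continuous voxel index/indices ``ijk``."""
    ijk = np.asarray(ijk, dtype=float)
    return grid.origin + ijk * grid.spacing


def sample_trilinear(grid: VoxelGrid, p):
    """Trilinear interpolation of grid values at world point(s) ``p``.

    Exact at voxel centers.  Points up to half a voxel beyond the extreme
    centers are clamped to the edge value; beyond that an
    :class:`OutsideGridError` is raised.
    """
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    ci = world_to_index(grid, pts)
    dims = np.array(grid.dims, dtype=float)
    if np.any(ci < -0.5 - 1e-9) or np.any(ci > dims - 0.5 + 1e-9):
        raise OutsideGridError("point(s) outside grid bounding box")
    ci = np.clip(ci, 0.0, dims - 1.0)
    out = ndimage.map_coordinates(
        np.asarray(grid.values, dtype=float), ci.T, order=1, mode="nearest"
    )
    return float(out[0]) if single else out
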