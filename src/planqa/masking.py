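"""Evaluation-mask construction.

The gamma comparison volume is the patient body minus a skin margin — eroded
slice by slice in 2D so axial planes never influence each other — intersected
with a low-dose threshold region computed from the reference dose.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BinaryMask, DoseGrid, GeometryError, VoxelGrid

__all__ = [
    "extract_body_mask",
    "erode_mask_2d",
    "low_dose_threshold_mask",
    "evaluation_mask",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def extract_body_mask(image: VoxelGrid, hu_threshold: float = -300.0) -> BinaryMask:
    """Segment the patient body from a CT image.

    Thresholds at ``hu_threshold``, keeps the largest 26-connected component
    and fills internal cavities slice-wise (axial planes, i.e. along the last
    axis).
    """
    fg = np.asarray(image.values) > hu_threshold
    if not fg.any():
        raise ValueError("empty body mask: no voxels above HU threshold")
    if fg.all():
        raise ValueError("body mask covers entire grid: no air background found")
    labels, n = ndimage.label(fg, structure=_CONN26)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    body = labels == int(np.argmax(sizes))
    for k in range(body.shape[2]):
        body[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return BinaryMask.like(image, body)


def _inplane_radii_voxels(spacing: np.ndarray, margin_mm: float) -> tuple[int, int]:
    return int(round(margin_mm / spacing[0])), int(round(margin_mm / spacing[1]))


def disk_structure(rx: int, ry: int) -> np.ndarray:
    """2D structuring element: offsets with (dx/rx)^2 + (dy/ry)^2 <= 1.

    For isotropic in-plane spacing (``rx == ry``) this is the discrete disk of
    Euclidean radius ``rx`` voxels.
    """
    dx = np.arange(-rx, rx + 1, dtype=float)
    dy = np.arange(-ry, ry + 1, dtype=float)
    ex = (dx / max(rx, 1)) ** 2 if rx > 0 else (dx != 0) * np.inf
    ey = (dy / max(ry, 1)) ** 2 if ry > 0 else (dy != 0) * np.inf
    return (ex[:, None] + ey[None, :]) <= 1.0 + 1e-9


def erode_mask_2d(mask: BinaryMask, margin_mm: float = 20.0) -> BinaryMask:
    """Erode each axial slice independently by a disk of radius ``margin_mm``.

    The disk radius in voxels is ``round(margin_mm / in-plane spacing)`` per
    axis.  Implemented via the per-slice Euclidean distance transform, which
    is exactly equivalent to erosion with the discrete disk element (a pixel
    survives iff no background pixel lies within the disk) but much faster
    for large margins.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    rx, ry = _inplane_radii_voxels(mask.spacing, margin_mm)
    if rx == 0 and ry == 0:
        return BinaryMask(mask.origin, mask.spacing, mask.values.copy())
    out = np.empty_like(mask.values)
    if rx == 0 or ry == 0:
        # degenerate line element; cheap direct erosion
        foot = disk_structure(rx, ry)[:, :, None]
        out = ndimage.binary_erosion(mask.values, structure=foot, border_value=0)
        return BinaryMask(mask.origin, mask.spacing, out)
    for k in range(mask.values.shape[2]):
        sl = mask.values[:, :, k]
        if not sl.any():
            out[:, :, k] = False
            continue
        # pad with background so the image border erodes like standard
        # structuring-element morphology (outside counts as background)
        padded = np.pad(sl, 1, mode="constant", constant_values=False)
        dist = ndimage.distance_transform_edt(padded, sampling=(1.0 / rx, 1.0 / ry))
        out[:, :, k] = dist[1:-1, 1:-1] > 1.0 + 1e-9
    return BinaryMask(mask.origin, mask.spacing, out)


def low_dose_threshold_mask(ref: DoseGrid, fraction: float = 0.20) -> BinaryMask:
    """Voxels receiving at least ``fraction`` of the maximum reference dose.

    Note the ``fraction == 0`` edge: every voxel satisfies ``dose >= 0``, so
    the mask is all-true.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    vals = np.asarray(ref.grid.values, dtype=float)
    dmax = float(vals.max())
    if dmax <= 0:
        raise ValueError("reference dose is all zero; threshold undefined")
    return BinaryMask.like(ref.grid, vals >= fraction * dmax)


def evaluation_mask(
    body: BinaryMask, eroded: BinaryMask, dose_mask: BinaryMask
) -> BinaryMask:
    """Voxelwise AND of the eroded body mask and the dose-threshold mask."""
    if not (body.same_lattice(eroded) and body.same_lattice(dose_mask)):
        raise GeometryError("masks must share one lattice")
    if np.any(eroded.values & ~body.values):
        raise ValueError("eroded mask is not a subset of the body mask")
    return BinaryMask(body.origin, body.spacing, eroded.values & dose_mask.values)
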