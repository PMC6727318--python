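"""Fiducial-marker geometry QA.

Each marker's distance to the marker-set centroid is compared between the
MRI-derived and CT marker sets.  The metric is invariant to rigid rotation
and translation of either set — deliberately so, since the two scans are in
different frames and the prostate may rotate between them — while remaining
sensitive to any change of the internal marker geometry (e.g. a misidentified
marker or a scaling error).
"""

from __future__ import annotations

import dataclasses
from itertools import permutations

import numpy as np

from .core import FiducialSet

__all__ = ["FiducialQAResult", "centroid", "match_markers", "fiducial_qa"]

_MAX_MATCH_N = 6  # exhaustive matching is n!; keep it honest


@dataclasses.dataclass
class FiducialQAResult:
    """Per-marker centroid-distance comparison between two modalities."""

    labels: tuple[str, ...]  # MRI-side labels, in reported order
    d_mri_mm: np.ndarray
    d_ct_mm: np.ndarray
    diff_mm: np.ndarray  # d_mri - d_ct, signed
    max_abs_diff_mm: float
    rms_diff_mm: float
    tolerance_mm: float
    passed: bool
    correspondence: dict[str, str]  # MRI label -> CT label


def centroid(fset: FiducialSet) -> np.ndarray:
    """Arithmetic mean of the marker coordinates (mm)."""
    return fset.points.mean(axis=0)


def _rigid_residual(pa: np.ndarray, pb: np.ndarray) -> float:
    """Min over proper rotations of sum ||pa - R pb||^2 (sets pre-centered)."""
    h = pb.T @ pa
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    trace = s[0] + s[1] + sign * s[2]
    return float(max(np.sum(pa**2) + np.sum(pb**2) - 2.0 * trace, 0.0))


def match_markers(a: FiducialSet, b: FiducialSet) -> dict[str, str]:
    """Correspondence between two marker sets of equal cardinality.

    Both sets are translated to their centroids; for each permutation the
    residual after optimal rigid (rotation + translation) alignment is
    evaluated exhaustively and the minimizing permutation chosen.  Because
    the residual is rigid-invariant, matching is unaffected by prostate
    rotation between scans.  Ties (within 1e-9 mm^2) are broken by
    lexicographic order of the assigned ``b`` labels.
    """
    if len(a) != len(b):
        raise ValueError("marker sets have unequal cardinality")
    n = len(a)
    if n > _MAX_MATCH_N:
        raise ValueError(f"exhaustive matching limited to n <= {_MAX_MATCH_N}")
    pa = a.points - centroid(a)
    pb = b.points - centroid(b)
    order_b = sorted(range(n), key=lambda i: b.labels[i])
    best_cost = np.inf
    best_perm: tuple[int, ...] | None = None
    for perm in permutations(order_b):  # lexicographic in b labels
        cost = _rigid_residual(pa, pb[list(perm)])
        if cost < best_cost - 1e-9:
            best_cost = cost
            best_perm = perm
    assert best_perm is not None
    return {a.labels[i]: b.labels[j] for i, j in enumerate(best_perm)}


def fiducial_qa(
    mri: FiducialSet, ct: FiducialSet, tol_mm: float = 1.0
) -> FiducialQAResult:
    """Compare per-marker distances to centroid between MRI and CT sets.

    Pass iff every ``|d_mri - d_ct|`` is within ``tol_mm`` (inclusive).
    """
    corr = match_markers(mri, ct)
    c_mri = centroid(mri)
    c_ct = centroid(ct)
    labels = mri.labels
    d_mri = np.array(
        [np.linalg.norm(mri.point(lab) - c_mri) for lab in labels]
    )
    d_ct = np.array(
        [np.linalg.norm(ct.point(corr[lab]) - c_ct) for lab in labels]
    )
    diff = d_mri - d_ct
    max_abs = float(np.max(np.abs(diff)))
    return FiducialQAResult(
        labels=labels,
        d_mri_mm=d_mri,
        d_ct_mm=d_ct,
        diff_mm=diff,
        max_abs_diff_mm=max_abs,
        rms_diff_mm=float(np.sqrt(np.mean(diff**2))),
        tolerance_mm=float(tol_mm),
        passed=bool(max_abs <= tol_mm + 1e-12),
        correspondence=corr,
    )
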