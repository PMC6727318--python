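"""Self-contained synthetic test cases: digital pelvis, pseudo-CT
perturbations, a toy dose engine and fiducial sets with controlled errors.

The dose engine is deliberately simple — equispaced axial beams with a smooth
lateral profile and pure exponential attenuation along the water-equivalent
path length (no scatter, no buildup).  It exists to make the QA metrics
exercisable and direction-correct, not to be dosimetrically accurate.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
from scipy import ndimage

from .core import BinaryMask, DoseGrid, FiducialSet, VoxelGrid, sample_trilinear

__all__ = [
    "PhantomSpec",
    "PerturbationSpec",
    "BeamSpec",
    "Phantom",
    "CaseBundle",
    "make_phantom",
    "make_pseudo_ct",
    "toy_dose_engine",
    "make_dose_pair",
    "make_case",
    "jitter_fiducials",
    "random_rigid_transform",
    "apply_rigid",
    "smooth_random_dose_pair",
]

AIR_HU = -1000.0
TISSUE_HU = 0.0


@dataclasses.dataclass
class PhantomSpec:
    """Digital pelvis: elliptic-cylinder body with bones, prostate, markers.

    ``seed`` perturbs the geometry slightly (semi-axes within +-4 %,
    structure centers within +-2 mm, fiducial offsets within +-1 mm) so that
    seeded cohorts are not identical; everything is deterministic given the
    seed.
    """

    body_semi_axes_mm: tuple[float, float] = (180.0, 120.0)
    body_length_mm: float = 200.0
    femoral_radius_mm: float = 22.0
    femoral_hu: float = 700.0
    ring_hu: float = 500.0
    prostate_radius_mm: float = 22.0
    prostate_hu: float = 30.0
    rectal_air_cavity: bool = False
    rectum_radius_mm: float = 12.0
    spacing_mm: float = 2.5
    grid_margin_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.body_semi_axes_mm) <= 0 or self.body_length_mm <= 0:
            raise ValueError("body dimensions must be positive")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")


@dataclasses.dataclass
class PerturbationSpec:
    """Controllable pseudo-CT discrepancy modes.

    ``skin_layer_mm`` adds an external soft-tissue shell by per-slice 2D
    dilation of the body contour, emulating the skin-expansion algorithm
    variant; ``contour_jitter_mm`` randomly displaces the body boundary;
    ``fiducial_sigma_mm`` is the isotropic Gaussian jitter per marker applied
    when deriving the MRI-side fiducial set.
    """

    tissue_hu_bias: float = 0.0
    bone_hu_bias: float = 0.0
    skin_layer_mm: float = 0.0
    contour_jitter_mm: float = 0.0
    fiducial_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("skin_layer_mm", "contour_jitter_mm", "fiducial_sigma_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass
class BeamSpec:
    """Toy treatment technique: equispaced coplanar beams in the axial plane."""

    n_beams: int = 7
    half_width_mm: float = 45.0
    prescription_gy: float = 60.0
    mu_eff_per_mm: float = 0.005
    gantry_start_deg: float = 0.0
    flat_fraction: float = 0.8  # lateral profile is flat out to this fraction

    def __post_init__(self) -> None:
        if self.n_beams < 1:
            raise ValueError("n_beams must be >= 1")
        if self.mu_eff_per_mm <= 0:
            raise ValueError("mu_eff_per_mm must be > 0")
        if self.half_width_mm <= 0 or self.prescription_gy <= 0:
            raise ValueError("half_width_mm and prescription_gy must be > 0")
        if not (0 < self.flat_fraction < 1):
            raise ValueError("flat_fraction must be in (0, 1)")


@dataclasses.dataclass
class Phantom:
    ct: VoxelGrid
    masks: dict[str, BinaryMask]
    fiducials_ct: FiducialSet
    isocenter: np.ndarray
    geometry: dict[str, Any]


@dataclasses.dataclass
class CaseBundle:
    """Everything the TPS would hold at QA time, for one case."""

    ct: VoxelGrid
    pseudo_ct: VoxelGrid
    ref_dose: DoseGrid
    eval_dose: DoseGrid
    fiducials_mri: FiducialSet
    fiducials_ct: FiducialSet
    manual_flags: dict[str, bool]
    case_id: str
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if len(self.fiducials_mri) != len(self.fiducials_ct):
            raise ValueError("fiducial sets must have equal cardinality")


# ---------------------------------------------------------------------------
# phantom construction

_FID_BASE_OFFSETS = np.array(
    [[8.0, 0.0, -6.0], [-7.0, 6.0, 5.0], [0.0, -7.0, 7.0]]
)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the synthetic pelvis CT, structure masks and CT fiducial set."""
    rng = np.random.default_rng(spec.seed)
    a0, b0 = spec.body_semi_axes_mm
    a = a0 * (1 + 0.04 * rng.uniform(-1, 1))
    b = b0 * (1 + 0.04 * rng.uniform(-1, 1))
    length = spec.body_length_mm
    s = float(spec.spacing_mm)
    m = spec.grid_margin_mm

    half_extent = np.array([a + m, b + m, length / 2 + m])
    dims = tuple(int(np.ceil(2 * h / s)) + 1 for h in half_extent)
    origin = -(np.array(dims) - 1) / 2.0 * s
    spacing = np.full(3, s)

    x = origin[0] + s * np.arange(dims[0])
    y = origin[1] + s * np.arange(dims[1])
    z = origin[2] + s * np.arange(dims[2])
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]

    body = ((X / a) ** 2 + (Y / b) ** 2 <= 1.0) & (np.abs(Z) <= length / 2)
    if not body.any():
        raise ValueError("phantom body is empty on this grid")
    if body[0, :, :].any() or body[-1, :, :].any() or body[:, 0, :].any() or body[:, -1, :].any():
        raise ValueError("phantom body exceeds the grid")

    def sphere(center: np.ndarray, radius: float) -> np.ndarray:
        return (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (
            Z - center[2]
        ) ** 2 <= radius**2

    jit = lambda: rng.uniform(-2.0, 2.0, size=3)  # noqa: E731

    prostate_center = np.array([0.0, 0.0, 0.0]) + jit()
    fem_l = np.array([0.78 * a, 0.0, 0.0]) + jit()
    fem_r = np.array([-0.78 * a, 0.0, 0.0]) + jit()
    fr = spec.femoral_radius_mm
    femoral = sphere(fem_l, fr) | sphere(fem_r, fr)

    ring_oa, ring_ob = 0.70 * a, 0.65 * b
    ring_ia, ring_ib = 0.60 * a, 0.50 * b
    ring_half_z = min(60.0, length / 2 - 5.0)
    r_out = (X / ring_oa) ** 2 + (Y / ring_ob) ** 2 <= 1.0
    r_in = (X / ring_ia) ** 2 + (Y / ring_ib) ** 2 <= 1.0
    ring = r_out & ~r_in & (np.abs(Z) <= ring_half_z)

    prostate = sphere(prostate_center, spec.prostate_radius_mm)
    bone = (femoral | ring) & body & ~prostate

    hu = np.full(dims, AIR_HU)
    hu[body] = TISSUE_HU
    hu[ring & body & ~prostate] = spec.ring_hu
    hu[femoral & body & ~prostate] = spec.femoral_hu
    hu[prostate & body] = spec.prostate_hu
    if spec.rectal_air_cavity:
        rectum_center = prostate_center + np.array([0.0, 40.0, 0.0])
        cavity = sphere(rectum_center, spec.rectum_radius_mm) & body & ~bone & ~prostate
        hu[cavity] = AIR_HU

    for name, mask in (("bone", bone), ("prostate", prostate & body)):
        if np.any(mask & ~body):
            raise ValueError(f"structure {name!r} exceeds the body")

    grid = VoxelGrid(origin, spacing, hu)
    offsets = _FID_BASE_OFFSETS + rng.uniform(-1.0, 1.0, size=(3, 3))
    points = prostate_center[None, :] + offsets
    fiducials = FiducialSet(("F1", "F2", "F3"), points, "CT")

    masks = {
        "body": BinaryMask.like(grid, body),
        "bone": BinaryMask.like(grid, bone),
        "prostate": BinaryMask.like(grid, prostate & body),
    }
    geometry = {
        "semi_axes_mm": (a, b),
        "length_mm": length,
        "prostate_center": prostate_center,
        "femoral_centers": (fem_l, fem_r),
    }
    return Phantom(grid, masks, fiducials, prostate_center, geometry)


# ---------------------------------------------------------------------------
# pseudo-CT perturbation


def _signed_distance_2d(body_slice: np.ndarray, spacing) -> np.ndarray:
    """Per-slice signed distance to the body boundary (positive outside)."""
    samp = (spacing[0], spacing[1])
    outside = ndimage.distance_transform_edt(~body_slice, sampling=samp)
    inside = ndimage.distance_transform_edt(body_slice, sampling=samp)
    return outside - inside


def make_pseudo_ct(
    ct: VoxelGrid, masks: dict[str, BinaryMask], perturb: PerturbationSpec
) -> VoxelGrid:
    """Apply the configured HU discrepancy modes to a copy of the CT."""
    if not ct.same_lattice(masks["body"]):
        raise ValueError("mask geometry does not match CT")
    rng = np.random.default_rng(perturb.seed)
    vals = np.asarray(ct.values, dtype=float).copy()
    body = masks["body"].values
    bone = masks["bone"].values
    tissue = body & ~bone & (vals > -500.0)  # exclude internal air cavities

    if perturb.contour_jitter_mm > 0:
        noise = ndimage.gaussian_filter(
            rng.standard_normal(vals.shape), sigma=3.0
        )
        noise /= max(noise.std(), 1e-12)
        new_body = np.empty_like(body)
        for k in range(vals.shape[2]):
            sd = _signed_distance_2d(body[:, :, k], ct.spacing)
            new_body[:, :, k] = sd <= noise[:, :, k] * perturb.contour_jitter_mm
        added = new_body & ~body
        removed = body & ~new_body
        vals[added] = TISSUE_HU
        vals[removed] = AIR_HU
        body = new_body
        tissue = tissue & body | added

    if perturb.skin_layer_mm > 0:
        # Add the shell with partial-volume weighting: an outside pixel whose
        # extent [d - s, d] from the body surface overlaps the layer [0, L]
        # gets the HU of that covered fraction.  This adds ~L mm of
        # water-equivalent path in the surface-normal direction regardless of
        # the voxel size (a binary shell would vanish on coarse grids).
        s_in = float(min(ct.spacing[0], ct.spacing[1]))
        layer = perturb.skin_layer_mm
        for k in range(vals.shape[2]):
            sl = body[:, :, k]
            if not sl.any():
                continue
            dist = ndimage.distance_transform_edt(
                ~sl, sampling=(ct.spacing[0], ct.spacing[1])
            )
            frac = np.clip((layer - (dist - s_in)) / s_in, 0.0, 1.0)
            frac[sl] = 0.0
            sel = frac > 0
            vals[:, :, k][sel] = np.maximum(
                vals[:, :, k][sel], AIR_HU + frac[sel] * (TISSUE_HU - AIR_HU)
            )
            tissue[:, :, k] |= frac >= 0.5

    if perturb.tissue_hu_bias != 0:
        vals[tissue] += perturb.tissue_hu_bias
    if perturb.bone_hu_bias != 0:
        vals[bone] += perturb.bone_hu_bias

    return VoxelGrid(ct.origin, ct.spacing, vals)


# ---------------------------------------------------------------------------
# toy dose engine


def hu_to_density(hu: np.ndarray) -> np.ndarray:
    """Piecewise-linear CT calibration: rho = 1 + HU/1000, clipped to [0, 2]."""
    return np.clip(1.0 + np.asarray(hu, dtype=float) / 1000.0, 0.0, 2.0)


def _lateral_profile(q: np.ndarray, flat: float) -> np.ndarray:
    """Flat-top profile with a cos^2 rolloff between ``flat`` and 1."""
    q = np.abs(q)
    out = np.zeros_like(q)
    out[q <= flat] = 1.0
    pen = (q > flat) & (q < 1.0)
    out[pen] = np.cos(0.5 * np.pi * (q[pen] - flat) / (1.0 - flat)) ** 2
    return out


def _beam_directions(beams: BeamSpec) -> np.ndarray:
    ang = np.deg2rad(beams.gantry_start_deg) + 2 * np.pi * np.arange(
        beams.n_beams
    ) / beams.n_beams
    return np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)


def _raw_dose(image: VoxelGrid, beams: BeamSpec, isocenter: np.ndarray) -> np.ndarray:
    """Unscaled dose array: sum over beams of profile * exp(-mu * WEPL).

    WEPL is computed on a beam-aligned ray bundle: density is trilinearly
    sampled at pitch ``h = min(spacing)/2`` along rays covering the aperture,
    cumulatively summed along the beam axis, and the resulting water-equivalent
    depth field is interpolated back at the target voxels.
    """
    rho = hu_to_density(image.values)
    # one zero voxel of padding lets out-of-grid samples clamp to air cheaply
    rho_pad = np.pad(rho, 1, mode="constant", constant_values=0.0)
    dims = np.array(image.dims)
    spacing = image.spacing
    origin = image.origin
    h = float(np.min(spacing)) / 2.0  # ray integration step and bundle pitch

    x = origin[0] + spacing[0] * np.arange(dims[0])
    y = origin[1] + spacing[1] * np.arange(dims[1])
    z = origin[2] + spacing[2] * np.arange(dims[2])
    hw = beams.half_width_mm
    pw_z = _lateral_profile((z - isocenter[2]) / hw, beams.flat_fraction)

    # rays start half a bounding-box diagonal upstream of the isocenter plane
    half_diag = 0.5 * float(np.linalg.norm(image.bbox_max - image.bbox_min))
    reach = half_diag + 2 * h
    ns = int(np.ceil(2 * reach / h)) + 2
    n_half = int(np.ceil(hw / h)) + 2
    lat = h * np.arange(-n_half, n_half + 1)  # ray offsets across the aperture
    dose = np.zeros(image.dims)

    def pad_sample(pts: np.ndarray) -> np.ndarray:
        ci = (pts - origin) / spacing + 1.0  # +1 for the zero-padding layer
        return ndimage.map_coordinates(
            rho_pad, ci.reshape(-1, 3).T, order=1, mode="nearest"
        )

    for d in _beam_directions(beams):
        e_u = np.array([-d[1], d[0], 0.0])  # in-plane, perpendicular to beam
        relx = x - isocenter[0]
        rely = y - isocenter[1]
        u2d = -relx[:, None] * d[1] + rely[None, :] * d[0]
        prof2d = _lateral_profile(u2d / hw, beams.flat_fraction)
        prof = prof2d[:, :, None] * pw_z[None, None, :]
        sel = np.nonzero(prof > 0)
        if sel[0].size == 0:
            continue

        # bundle sample positions: (u, z-offset, depth along beam)
        s_mid = (np.arange(ns) + 0.5) * h
        bundle = (
            isocenter[None, None, None, :]
            + lat[:, None, None, None] * e_u[None, None, None, :]
            + lat[None, :, None, None] * np.array([0.0, 0.0, 1.0])
            + (s_mid[None, None, :, None] - reach) * d[None, None, None, :]
        )
        vals = pad_sample(bundle).reshape(lat.size, lat.size, ns)
        depth = np.cumsum(vals, axis=2) * h  # integral from upstream to s

        pts = np.stack([x[sel[0]], y[sel[1]], z[sel[2]]], axis=1)
        rel = pts - isocenter
        u = rel @ e_u
        w = rel[:, 2]
        s = rel @ d + reach
        idx = np.stack(
            [u / h + n_half, w / h + n_half, s / h - 1.0], axis=0
        )
        wepl = ndimage.map_coordinates(depth, idx, order=1, mode="nearest")
        dose[sel] += prof[sel] * np.exp(-beams.mu_eff_per_mm * wepl)
    return dose


def toy_dose_engine(
    image: VoxelGrid,
    beams: BeamSpec,
    isocenter,
    *,
    scale: float | None = None,
) -> DoseGrid:
    """Compute a dose distribution on ``image``.

    With ``scale=None`` the dose is normalized so the isocenter receives
    ``beams.prescription_gy`` (a self-consistent "plan").  Passing an explicit
    ``scale`` reuses another plan's monitor units, emulating recalculation of
    the same plan on a different image.
    """
    isocenter = np.asarray(isocenter, dtype=float)
    if sample_trilinear(image, isocenter) <= -300.0:
        raise ValueError("isocenter lies outside the body")
    raw = _raw_dose(image, beams, isocenter)
    grid = VoxelGrid(image.origin, image.spacing, raw)
    iso_raw = sample_trilinear(grid, isocenter)
    if scale is None:
        if iso_raw <= 0:
            raise ValueError("zero raw dose at isocenter")
        scale = beams.prescription_gy / iso_raw
    grid.values *= scale
    return DoseGrid(grid, isocenter)


def _plan_scale(image: VoxelGrid, beams: BeamSpec, isocenter: np.ndarray) -> float:
    raw = _raw_dose(image, beams, isocenter)
    iso_raw = sample_trilinear(VoxelGrid(image.origin, image.spacing, raw), isocenter)
    if iso_raw <= 0:
        raise ValueError("zero raw dose at isocenter")
    return beams.prescription_gy / iso_raw


def make_dose_pair(
    planning_image: VoxelGrid,
    recalc_image: VoxelGrid,
    beams: BeamSpec,
    isocenter,
) -> tuple[DoseGrid, DoseGrid]:
    """(plan dose, recalculated dose) sharing one set of monitor units.

    The plan is normalized to prescription at the isocenter on
    ``planning_image``; the recalculation applies the identical scale on
    ``recalc_image``.
    """
    isocenter = np.asarray(isocenter, dtype=float)
    scale = _plan_scale(planning_image, beams, isocenter)
    plan = toy_dose_engine(planning_image, beams, isocenter, scale=scale)
    recalc = toy_dose_engine(recalc_image, beams, isocenter, scale=scale)
    return plan, recalc


def smooth_random_dose_pair(
    seed: int,
    n: int = 30,
    spacing_mm: float = 1.5,
    rel_amp: float = 0.03,
    abs_amp_fraction: float = 0.01,
    max_dose_gy: float = 2.0,
):
    """A (reference, evaluated, mask) triple of smooth correlated doses.

    The reference is a smoothed random field scaled to ``max_dose_gy``; the
    evaluated dose adds a smooth multiplicative (``rel_amp``) and additive
    (``abs_amp_fraction`` of max) perturbation.  The mask keeps voxels at or
    above 20 % of the reference maximum.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ref = ndimage.gaussian_filter(rng.random((n, n, n)), 3.0)
    ref = (ref - ref.min()) / (ref.max() - ref.min()) * max_dose_gy
    pert = ndimage.gaussian_filter(rng.standard_normal((n, n, n)), 4.0)
    pert /= max(np.abs(pert).max(), 1e-12)
    ev = np.clip(ref * (1 + rel_amp * pert) + abs_amp_fraction * max_dose_gy * pert, 0, None)
    origin = -np.ones(3) * (n - 1) / 2.0 * spacing_mm
    spacing = np.full(3, spacing_mm)
    iso = np.zeros(3)
    ref_d = DoseGrid(VoxelGrid(origin, spacing, ref), iso)
    ev_d = DoseGrid(VoxelGrid(origin, spacing, ev), iso)
    mask = BinaryMask(origin, spacing, ref >= 0.2 * ref.max())
    return ref_d, ev_d, mask


# ---------------------------------------------------------------------------
# fiducial perturbation and full cases


def random_rigid_transform(
    rng: np.random.Generator,
    max_angle_deg: float = 10.0,
    max_translation_mm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A random small rotation matrix and translation vector."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    kx, ky, kz = axis
    k_cross = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    rot = (
        np.eye(3)
        + np.sin(angle) * k_cross
        + (1 - np.cos(angle)) * (k_cross @ k_cross)
    )
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return rot, t


def apply_rigid(
    fset: FiducialSet, rot: np.ndarray, t: np.ndarray, modality: str | None = None
) -> FiducialSet:
    pts = fset.points @ np.asarray(rot).T + np.asarray(t)
    return FiducialSet(fset.labels, pts, modality or fset.modality)


def jitter_fiducials(
    fset: FiducialSet,
    sigma_mm: float,
    rng: np.random.Generator,
    modality: str = "MRI",
) -> FiducialSet:
    """Add isotropic Gaussian jitter (per marker, per axis) to a marker set."""
    noise = rng.normal(0.0, sigma_mm, size=fset.points.shape) if sigma_mm > 0 else 0.0
    return FiducialSet(fset.labels, fset.points + noise, modality)


from .report import CHECKLIST_LABELS  # noqa: E402  (avoid circular import at top)


def make_case(
    spec: PhantomSpec,
    perturb: PerturbationSpec,
    beams: BeamSpec,
    case_id: str = "synthetic",
) -> CaseBundle:
    """Full synthetic case with ground truth attached.

    The plan is computed on the pseudo-CT (the evaluated dose) and
    recalculated with the same monitor units on the CT (the reference dose).
    The MRI fiducial set is a small random rigid transform of the CT set plus
    per-marker Gaussian jitter of ``perturb.fiducial_sigma_mm``.
    """
    phantom = make_phantom(spec)
    pseudo = make_pseudo_ct(phantom.ct, phantom.masks, perturb)
    eval_dose, ref_dose = make_dose_pair(
        pseudo, phantom.ct, beams, phantom.isocenter
    )
    rng = np.random.default_rng(perturb.seed + 1)
    rot, t = random_rigid_transform(rng, max_angle_deg=5.0, max_translation_mm=8.0)
    fid_mri = jitter_fiducials(
        apply_rigid(phantom.fiducials_ct, rot, t, modality="MRI"),
        perturb.fiducial_sigma_mm,
        rng,
    )
    manual_flags = {lab: True for lab in CHECKLIST_LABELS if _is_manual(lab)}
    truth = {
        "perturbation": dataclasses.asdict(perturb),
        "phantom_geometry": phantom.geometry,
        "rigid": (rot, t),
    }
    return CaseBundle(
        ct=phantom.ct,
        pseudo_ct=pseudo,
        ref_dose=ref_dose,
        eval_dose=eval_dose,
        fiducials_mri=fid_mri,
        fiducials_ct=phantom.fiducials_ct,
        manual_flags=manual_flags,
        case_id=case_id,
        ground_truth=truth,
    )


def _is_manual(label: str) -> bool:
    from .report import CHECKLIST_KINDS

    return CHECKLIST_KINDS[label] == "manual"
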