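"""Readers and writers for volumes, doses, point sets, configs and reports.

Core formats are NIfTI (volumes and doses), CSV (fiducials) and YAML (config
and dose sidecars).  NIfTI stores geometry in RAS; everything here is
converted to/from the package-wide LPS world frame on the way through.
DICOM CT-series / RT Dose reading is an optional extension requiring
``pydicom``.

Every reader is total on its declared format: parse failures raise, nothing
is silently defaulted.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import (
    DoseGrid,
    FiducialSet,
    GammaCriteria,
    QATolerances,
    VoxelGrid,
)

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_dose",
    "write_dose",
    "read_fiducials",
    "write_fiducials",
    "write_report",
    "read_report",
    "load_config",
    "load_case",
    "write_case",
]


class FormatError(ValueError):
    """A file could not be parsed as its declared format."""


_LPS_FLIP = np.array([-1.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# NIfTI volumes


def _grid_to_nifti(grid: VoxelGrid) -> nib.Nifti1Image:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(_LPS_FLIP * grid.spacing)
    affine[:3, 3] = _LPS_FLIP * grid.origin
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float64), affine)
    img.header.set_data_dtype(np.float64)
    return img


def _nifti_to_grid(img: nib.Nifti1Image, path) -> VoxelGrid:
    affine = np.asarray(img.affine, dtype=float)
    lin = affine[:3, :3]
    if np.any(np.abs(lin - np.diag(np.diag(lin))) > 1e-6 * max(1.0, np.abs(lin).max())):
        raise FormatError(
            f"{path}: oblique-unsupported (direction matrix is not diagonal)"
        )
    vals = np.asarray(img.get_fdata(), dtype=np.float64)
    if vals.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got ndim={vals.ndim}")
    step_lps = _LPS_FLIP * np.diag(lin)
    origin_lps = _LPS_FLIP * affine[:3, 3]
    # canonicalize axes so LPS spacing is positive
    for ax in range(3):
        if step_lps[ax] < 0:
            vals = np.flip(vals, axis=ax)
            origin_lps[ax] = origin_lps[ax] + (vals.shape[ax] - 1) * step_lps[ax]
            step_lps[ax] = -step_lps[ax]
        elif step_lps[ax] == 0:
            raise FormatError(f"{path}: degenerate voxel spacing on axis {ax}")
    return VoxelGrid(origin_lps, step_lps, np.ascontiguousarray(vals))


def read_volume(path, format: str = "nifti") -> VoxelGrid:
    """Read a 3D scalar volume into the LPS-mm world frame."""
    path = Path(path)
    if format == "nifti":
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
        return _nifti_to_grid(img, path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown volume format {format!r}")


def write_volume(grid: VoxelGrid, path) -> None:
    nib.save(_grid_to_nifti(grid), str(path))


# ---------------------------------------------------------------------------
# doses


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".yaml")
    return path.with_suffix(".yaml")


def read_dose(path, format: str = "nifti", isocenter=None) -> DoseGrid:
    """Read a dose grid in Gy plus its isocenter.

    For NIfTI the isocenter comes from the ``isocenter`` argument or from a
    YAML sidecar (``<stem>.yaml`` with key ``isocenter_mm``).  For DICOM RT
    Dose, ``DoseGridScaling`` is applied; the isocenter must be supplied.
    """
    path = Path(path)
    if format == "nifti":
        grid = read_volume(path, "nifti")
    elif format == "dicom_rtdose":
        grid = _read_dicom_rtdose(path)
    else:
        raise ValueError(f"unknown dose format {format!r}")
    if np.any(grid.values < -1e-9):
        raise ValueError(f"{path}: negative dose values after scaling")
    if isocenter is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(
                f"{path}: no isocenter supplied and no sidecar {sidecar.name}"
            )
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        if not isinstance(meta, dict) or "isocenter_mm" not in meta:
            raise FormatError(f"{sidecar}: missing key 'isocenter_mm'")
        isocenter = meta["isocenter_mm"]
    return DoseGrid(grid, np.asarray(isocenter, dtype=float))


def write_dose(dose: DoseGrid, path) -> None:
    """Write a dose as NIfTI plus a YAML sidecar holding the isocenter."""
    path = Path(path)
    write_volume(dose.grid, path)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(
            {"isocenter_mm": [float(v) for v in dose.isocenter]}, fh
        )


# ---------------------------------------------------------------------------
# fiducial CSV

_FID_HEADER = ["label", "x_mm", "y_mm", "z_mm", "modality"]


def read_fiducials(path) -> FiducialSet:
    """Read a marker set from CSV (``label,x_mm,y_mm,z_mm,modality``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            f.strip() for f in reader.fieldnames
        ] != _FID_HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(_FID_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        rows = list(reader)
    if len(rows) < 3:
        raise ValueError("at least 3 markers required")
    labels = [r["label"].strip() for r in rows]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate marker labels")
    try:
        points = np.array(
            [[float(r["x_mm"]), float(r["y_mm"]), float(r["z_mm"])] for r in rows]
        )
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric coordinate ({exc})") from exc
    modalities = {r["modality"].strip() for r in rows}
    if len(modalities) != 1:
        raise FormatError(f"{path}: mixed modalities {sorted(modalities)}")
    return FiducialSet(tuple(labels), points, modalities.pop())


def write_fiducials(fset: FiducialSet, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FID_HEADER)
        for lab, p in zip(fset.labels, fset.points):
            writer.writerow([lab, repr(float(p[0])), repr(float(p[1])),
                             repr(float(p[2])), fset.modality])


# ---------------------------------------------------------------------------
# reports


def write_report(report, path, format: str = "json") -> None:
    """Serialize a QA report deterministically as JSON or readable text."""
    path = Path(path)
    d = report.to_dict()
    if format == "json":
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "text":
        lines = [f"QA report — case {d['case_id']}", ""]
        for it in d["checklist"]:
            mark = {"pass": "✓", "fail": "✗", "not_assessed": "?"}[it["status"]]
            ev = ", ".join(f"{k}={_fmt(v)}" for k, v in sorted(it["evidence"].items()))
            lines.append(f"[{mark}] {it['label']} ({it['kind']})" + (f": {ev}" if ev else ""))
        lines.append("")
        lines.append(f"OVERALL: {'PASS' if d['overall_pass'] else 'FAIL'}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> tuple[QATolerances, list[GammaCriteria], dict[str, bool]]:
    """Load tolerances, gamma criteria and manual checklist flags from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    tolerances = QATolerances(**(cfg.get("tolerances") or {}))
    crit_cfg = cfg.get("criteria")
    if crit_cfg:
        criteria = [GammaCriteria(**c) for c in crit_cfg]
    else:
        from .report import default_criteria

        criteria = default_criteria()
    flags = cfg.get("manual_flags") or {}
    if not isinstance(flags, dict):
        raise FormatError(f"{path}: manual_flags must be a mapping")
    return tolerances, criteria, {str(k): bool(v) for k, v in flags.items()}


def load_case(path):
    """Load a full case bundle from a YAML file referencing its data files.

    Keys: ``case_id``, ``ct``, ``pseudo_ct``, ``ref_dose``, ``eval_dose``,
    ``fiducials_mri``, ``fiducials_ct`` (paths relative to the YAML file) and
    optional ``manual_flags``.
    """
    from .synthetic import CaseBundle

    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: case file must be a mapping")
    base = path.parent
    required = ["ct", "pseudo_ct", "ref_dose", "eval_dose", "fiducials_mri", "fiducials_ct"]
    missing = [k for k in required if k not in cfg]
    if missing:
        raise FormatError(f"{path}: missing keys {missing}")
    flags = cfg.get("manual_flags") or {}
    return CaseBundle(
        ct=read_volume(base / cfg["ct"]),
        pseudo_ct=read_volume(base / cfg["pseudo_ct"]),
        ref_dose=read_dose(base / cfg["ref_dose"]),
        eval_dose=read_dose(base / cfg["eval_dose"]),
        fiducials_mri=read_fiducials(base / cfg["fiducials_mri"]),
        fiducials_ct=read_fiducials(base / cfg["fiducials_ct"]),
        manual_flags={str(k): bool(v) for k, v in flags.items()},
        case_id=str(cfg.get("case_id", path.stem)),
    )


def write_case(bundle, directory) -> Path:
    """Write a case bundle to ``directory`` and return the case YAML path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(bundle.ct, directory / "ct.nii")
    write_volume(bundle.pseudo_ct, directory / "pseudo_ct.nii")
    write_dose(bundle.ref_dose, directory / "ref_dose.nii")
    write_dose(bundle.eval_dose, directory / "eval_dose.nii")
    write_fiducials(bundle.fiducials_mri, directory / "fiducials_mri.csv")
    write_fiducials(bundle.fiducials_ct, directory / "fiducials_ct.csv")
    case = {
        "case_id": bundle.case_id,
        "ct": "ct.nii",
        "pseudo_ct": "pseudo_ct.nii",
        "ref_dose": "ref_dose.nii",
        "eval_dose": "eval_dose.nii",
        "fiducials_mri": "fiducials_mri.csv",
        "fiducials_ct": "fiducials_ct.csv",
        "manual_flags": {k: bool(v) for k, v in bundle.manual_flags.items()},
    }
    out = directory / "case.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(case, fh, sort_keys=False)
    return out


# ---------------------------------------------------------------------------
# DICOM extension (requires pydicom)


def _require_pydicom():
    try:
        import pydicom  # noqa: F401

        return pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM support requires the optional 'pydicom' dependency "
            "(pip install planqa[dicom])"
        ) from exc


def _read_dicom_series(directory) -> VoxelGrid:
    """Read an axial CT series from a directory of DICOM slice files."""
    pydicom = _require_pydicom()
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    slices = []
    for f in sorted(directory.iterdir()):
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"{directory}: no DICOM image slices found")
    first = slices[0]
    iop = np.array(first.ImageOrientationPatient, dtype=float)
    if not (np.allclose(iop[:3], [1, 0, 0], atol=1e-6)
            and np.allclose(iop[3:], [0, 1, 0], atol=1e-6)):
        raise FormatError(f"{directory}: oblique-unsupported orientation {iop}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(slices) > 1:
        dz = np.diff(zpos)
        if np.any(dz <= 0) or np.ptp(dz) > 1e-3:
            raise FormatError(f"{directory}: non-uniform slice pitch")
        slice_pitch = float(dz[0])
    else:
        slice_pitch = float(getattr(first, "SliceThickness", 1.0))
    rows_sp, cols_sp = (float(v) for v in first.PixelSpacing)
    vol = np.stack(
        [
            ds.pixel_array.astype(np.float64) * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for ds in slices
        ],
        axis=-1,
    )
    # pixel_array is (row, col) = (y, x); transpose to (x, y, z)
    vol = np.ascontiguousarray(np.transpose(vol, (1, 0, 2)))
    origin = np.array(
        [
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            zpos[0],
        ]
    )
    spacing = np.array([cols_sp, rows_sp, slice_pitch])
    return VoxelGrid(origin, spacing, vol)


def _read_dicom_rtdose(path) -> VoxelGrid:
    """Read a DICOM RT Dose object, applying ``DoseGridScaling``."""
    pydicom = _require_pydicom()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise FormatError(f"{path}: not an RT Dose object")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    vol = ds.pixel_array.astype(np.float64) * scaling  # (frame, row, col)
    vol = np.ascontiguousarray(np.transpose(vol, (2, 1, 0)))  # -> (x, y, z)
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1 and np.ptp(np.diff(offsets)) > 1e-3:
        raise FormatError(f"{path}: non-uniform dose frame spacing")
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    rows_sp, cols_sp = (float(v) for v in ds.PixelSpacing)
    origin = np.array([float(v) for v in ds.ImagePositionPatient])
    origin[2] += offsets[0]
    return VoxelGrid(origin, np.array([cols_sp, rows_sp, abs(dz)]), vol)
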