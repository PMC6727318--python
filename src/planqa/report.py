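"""Per-case QA checklist aggregation and cohort summaries.

The checklist has nine fixed rows.  Six are visual judgments supplied by the
operator as boolean flags (an unsupplied flag is recorded as ``not_assessed``
and blocks the overall pass); three are automated: the isocenter dose check,
the dose-distribution gamma comparison and the fiducial-marker geometry
check.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Sequence

import numpy as np

from . import masking
from .align import align_by_isocenter, resample_pair_to_common, resample_to_lattice
from .core import GammaCriteria, GammaResult, QATolerances
from .fiducials import FiducialQAResult, fiducial_qa
from .gamma import IsoDoseCheck, compute_gamma, isocenter_dose_check

__all__ = [
    "CHECKLIST_LABELS",
    "CHECKLIST_KINDS",
    "ChecklistItem",
    "QAReport",
    "CohortSummary",
    "run_case_qa",
    "summarize_cohort",
    "default_criteria",
    "plot_bland_altman",
    "plot_difference_histogram",
]

#: the nine checklist rows, in table order
CHECKLIST_LABELS: tuple[str, ...] = (
    "Distortion correction",
    "Image transfer",
    "Image orientation and appearance",
    "Field of view",
    "Fiducial marker visibility",
    "Femoral heads",
    "Dose at isocenter",
    "Dose distribution",
    "Fiducial marker positions",
)

CHECKLIST_KINDS: dict[str, str] = {
    lab: ("automated" if lab in (
        "Dose at isocenter", "Dose distribution", "Fiducial marker positions"
    ) else "manual")
    for lab in CHECKLIST_LABELS
}

_STATUSES = ("pass", "fail", "not_assessed")


def default_criteria() -> list[GammaCriteria]:
    """The three standard gamma criteria sets, most permissive first."""
    return [
        GammaCriteria(3.0, 3.0),
        GammaCriteria(2.0, 2.0),
        GammaCriteria(2.0, 1.0),
    ]


@dataclasses.dataclass
class ChecklistItem:
    label: str
    kind: str  # manual | automated
    status: str  # pass | fail | not_assessed
    evidence: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"status must be one of {_STATUSES}")


@dataclasses.dataclass
class QAReport:
    """Per-case pass/fail ledger plus the numeric evidence for each item."""

    case_id: str
    checklist: list[ChecklistItem]
    gamma_results: list[GammaResult]
    iso_check: IsoDoseCheck | None
    fiducial_result: FiducialQAResult | None
    overall_pass: bool

    def item(self, label: str) -> ChecklistItem:
        for it in self.checklist:
            if it.label == label:
                return it
        raise KeyError(label)

    def to_dict(self) -> dict[str, Any]:
        """JSON-serializable summary (gamma maps are not embedded)."""
        gam = []
        for g in self.gamma_results:
            gam.append(
                {
                    "criteria": {
                        "dose_diff_pct": g.criteria.dose_diff_pct,
                        "dta_mm": g.criteria.dta_mm,
                        "low_dose_threshold_fraction": g.criteria.low_dose_threshold_fraction,
                        "normalization": g.criteria.normalization,
                    },
                    "pass_rate_pct": g.pass_rate_pct,
                    "mean_gamma": g.mean_gamma,
                    "n_evaluated": g.n_evaluated,
                }
            )
        iso = None
        if self.iso_check is not None:
            iso = dataclasses.asdict(self.iso_check)
        fid = None
        if self.fiducial_result is not None:
            f = self.fiducial_result
            fid = {
                "labels": list(f.labels),
                "d_mri_mm": [float(v) for v in f.d_mri_mm],
                "d_ct_mm": [float(v) for v in f.d_ct_mm],
                "diff_mm": [float(v) for v in f.diff_mm],
                "max_abs_diff_mm": f.max_abs_diff_mm,
                "rms_diff_mm": f.rms_diff_mm,
                "tolerance_mm": f.tolerance_mm,
                "passed": f.passed,
                "correspondence": dict(f.correspondence),
            }
        return {
            "case_id": self.case_id,
            "checklist": [
                {
                    "label": it.label,
                    "kind": it.kind,
                    "status": it.status,
                    "evidence": _jsonable(it.evidence),
                }
                for it in self.checklist
            ],
            "gamma_results": gam,
            "iso_check": _jsonable(iso),
            "fiducial_result": fid,
            "overall_pass": self.overall_pass,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "QAReport":
        import numpy as _np

        checklist = [
            ChecklistItem(it["label"], it["kind"], it["status"], it["evidence"])
            for it in d["checklist"]
        ]
        iso = None
        if d.get("iso_check") is not None:
            iso = IsoDoseCheck(**d["iso_check"])
        fid = None
        if d.get("fiducial_result") is not None:
            f = d["fiducial_result"]
            fid = FiducialQAResult(
                labels=tuple(f["labels"]),
                d_mri_mm=_np.array(f["d_mri_mm"]),
                d_ct_mm=_np.array(f["d_ct_mm"]),
                diff_mm=_np.array(f["diff_mm"]),
                max_abs_diff_mm=f["max_abs_diff_mm"],
                rms_diff_mm=f["rms_diff_mm"],
                tolerance_mm=f["tolerance_mm"],
                passed=f["passed"],
                correspondence=dict(f["correspondence"]),
            )
        return cls(
            case_id=d["case_id"],
            checklist=checklist,
            gamma_results=[],  # maps are not serialized
            iso_check=iso,
            fiducial_result=fid,
            overall_pass=d["overall_pass"],
        )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _select_checklist_criteria(criteria_list: Sequence[GammaCriteria]) -> GammaCriteria:
    """The criterion driving the pass/fail row: 2%/2 mm when present."""
    for c in criteria_list:
        if abs(c.dose_diff_pct - 2.0) < 1e-9 and abs(c.dta_mm - 2.0) < 1e-9:
            return c
    return criteria_list[0]


def run_case_qa(
    bundle,
    tolerances: QATolerances | None = None,
    criteria_list: Sequence[GammaCriteria] | None = None,
) -> QAReport:
    """Run the full QA pipeline on one case and fill the checklist.

    Stages: isocenter alignment, common-lattice resampling, body mask from
    the CT, 2D skin-margin erosion, low-dose thresholding, gamma per criteria
    set, isocenter dose check and fiducial QA.  Stage errors are trapped and
    recorded as failed checklist rows; a partial report is always returned.
    """
    tolerances = tolerances or QATolerances()
    criteria_list = list(criteria_list or default_criteria())

    items: dict[str, ChecklistItem] = {}
    for lab in CHECKLIST_LABELS:
        kind = CHECKLIST_KINDS[lab]
        if kind == "manual":
            flag = bundle.manual_flags.get(lab)
            if flag is None:
                status, ev = "not_assessed", {"source": "manual_flags", "flag": None}
            else:
                status = "pass" if flag else "fail"
                ev = {"source": "manual_flags", "flag": bool(flag)}
            items[lab] = ChecklistItem(lab, kind, status, ev)

    gamma_results: list[GammaResult] = []
    iso_check: IsoDoseCheck | None = None
    try:
        aligned_eval = align_by_isocenter(bundle.ref_dose, bundle.eval_dose)
        ref_r, eval_r = resample_pair_to_common(
            bundle.ref_dose, aligned_eval, tolerances.resample_mm
        )
        ct_r = resample_to_lattice(
            bundle.ct, ref_r.grid.origin, ref_r.grid.spacing, ref_r.grid.dims,
            cval=-1000.0,
        )
        body = masking.extract_body_mask(ct_r)
        eroded = masking.erode_mask_2d(body, tolerances.skin_margin_mm)

        for crit in criteria_list:
            dose_mask = masking.low_dose_threshold_mask(
                ref_r, crit.low_dose_threshold_fraction
            )
            ev_mask = masking.evaluation_mask(body, eroded, dose_mask)
            gamma_results.append(compute_gamma(ref_r, eval_r, crit, ev_mask))

        iso_check = isocenter_dose_check(ref_r, eval_r, tolerances.iso_dose_pct)
        items["Dose at isocenter"] = ChecklistItem(
            "Dose at isocenter",
            "automated",
            "pass" if iso_check.passed else "fail",
            {
                "ref_dose_gy": iso_check.ref_dose_gy,
                "eval_dose_gy": iso_check.eval_dose_gy,
                "diff_pct": iso_check.diff_pct,
                "tolerance_pct": iso_check.tolerance_pct,
            },
        )

        head = _select_checklist_criteria(criteria_list)
        gres = gamma_results[criteria_list.index(head)]
        if gres.n_evaluated == 0:
            items["Dose distribution"] = ChecklistItem(
                "Dose distribution", "automated", "fail",
                {"error": "empty evaluation mask", "n_evaluated": 0},
            )
        else:
            ok = gres.pass_rate_pct > tolerances.gamma_pass_pct
            items["Dose distribution"] = ChecklistItem(
                "Dose distribution",
                "automated",
                "pass" if ok else "fail",
                {
                    "criteria": head.label(),
                    "pass_rate_pct": gres.pass_rate_pct,
                    "mean_gamma": gres.mean_gamma,
                    "n_evaluated": gres.n_evaluated,
                    "required_pct": tolerances.gamma_pass_pct,
                },
            )
    except Exception as exc:  # stage failure -> failed rows, partial report
        for lab in ("Dose at isocenter", "Dose distribution"):
            if lab not in items:
                items[lab] = ChecklistItem(lab, "automated", "fail", {"error": str(exc)})

    fid_result: FiducialQAResult | None = None
    try:
        fid_result = fiducial_qa(
            bundle.fiducials_mri, bundle.fiducials_ct, tolerances.fiducial_tol_mm
        )
        items["Fiducial marker positions"] = ChecklistItem(
            "Fiducial marker positions",
            "automated",
            "pass" if fid_result.passed else "fail",
            {
                "max_abs_diff_mm": fid_result.max_abs_diff_mm,
                "rms_diff_mm": fid_result.rms_diff_mm,
                "diff_mm": [float(v) for v in fid_result.diff_mm],
                "tolerance_mm": fid_result.tolerance_mm,
            },
        )
    except Exception as exc:
        items["Fiducial marker positions"] = ChecklistItem(
            "Fiducial marker positions", "automated", "fail", {"error": str(exc)}
        )

    checklist = [items[lab] for lab in CHECKLIST_LABELS]
    overall = all(it.status == "pass" for it in checklist)
    return QAReport(
        case_id=bundle.case_id,
        checklist=checklist,
        gamma_results=gamma_results,
        iso_check=iso_check,
        fiducial_result=fid_result,
        overall_pass=overall,
    )


# ---------------------------------------------------------------------------
# cohort summaries


@dataclasses.dataclass
class CohortSummary:
    """Agreement statistics for one metric over a cohort.

    ``loa_low``/``loa_high`` are the mean +- 1.96 * SD limits of agreement;
    ``sd`` uses the sample (n-1) convention.
    """

    metric: str
    n: int
    mean: float
    sd: float
    loa_low: float
    loa_high: float
    rms: float
    min: float
    max: float


def summarize_cohort(values: Sequence[float], metric_name: str) -> CohortSummary:
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("cohort summary requires at least 2 values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return CohortSummary(
        metric=metric_name,
        n=int(vals.size),
        mean=mean,
        sd=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        rms=float(np.sqrt(np.mean(vals**2))),
        min=float(vals.min()),
        max=float(vals.max()),
    )


def plot_bland_altman(values: Sequence[float], metric_name: str):
    """Per-case differences with mean and limits-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = summarize_cohort(values, metric_name)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(range(1, s.n + 1), list(values), "o", color="tab:blue")
    ax.axhline(s.mean, color="k", label=f"mean {s.mean:.2f}")
    for y in (s.loa_low, s.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("case")
    ax.set_ylabel(metric_name)
    ax.legend()
    fig.tight_layout()
    return fig


def plot_difference_histogram(values: Sequence[float], metric_name: str, bins: int = 20):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(list(values), bins=bins, color="tab:gray", edgecolor="k")
    ax.set_xlabel(metric_name)
    ax.set_ylabel("count")
    fig.tight_layout()
    return fig
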