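# planqa

Quality assurance for MRI-only radiotherapy treatment plans.

When a prostate plan is created on a pseudo-CT (a CT-like image synthesised
from MRI) and verified against a conventional CT, three automated checks
decide whether the MRI-only plan is safe to treat with:

1. **Isocenter dose** — the point dose on the pseudo-CT must be within 2 %
   of the recalculation on the verification CT.
2. **Dose distribution** — a masked 3D gamma comparison (default criteria
   3 %/3 mm, 2 %/2 mm, 2 %/1 mm; 20 % low-dose threshold; body contour
   eroded by a 20 mm skin margin, slice by slice in 2D) must exceed a 90 %
   pass rate at 2 %/2 mm.
3. **Fiducial marker positions** — each implanted gold marker's distance to
   the marker-set centroid, compared between the MRI-derived and CT marker
   sets, must agree within 1.0 mm (rigid-invariant, so prostate rotation
   between scans does not trigger false failures).

These feed a nine-row per-case checklist (six visual items enter as operator
flags) with an overall pass/fail verdict, plus cohort summaries
(Bland–Altman limits, RMS, histograms).

A synthetic pelvis phantom and a toy exponential-attenuation dose engine
generate fully self-contained test cases with controllable pseudo-CT error
modes (tissue/bone HU bias, a 1 mm skin-expansion layer, contour jitter,
fiducial jitter), so every stage has a ground truth without any clinical
data.

## Layout

| module | contents |
| --- | --- |
| `planqa.core` | `VoxelGrid`, `DoseGrid`, `FiducialSet`, `GammaCriteria`, `QATolerances`, trilinear sampling |
| `planqa.io` | NIfTI volumes/doses (YAML isocenter sidecars), CSV fiducials, YAML config, JSON/text reports; optional DICOM readers (needs `pydicom`) |
| `planqa.align` | isocenter alignment, common-lattice 1.5 mm resampling |
| `planqa.masking` | body extraction, 2D skin-margin erosion, low-dose threshold, evaluation mask |
| `planqa.gamma` | 3D gamma engine + exhaustive brute-force oracle, isocenter dose check |
| `planqa.fiducials` | centroid-distance metric, exhaustive marker matching |
| `planqa.report` | checklist assembly (`run_case_qa`), cohort statistics, plots |
| `planqa.synthetic` | pelvis phantom, pseudo-CT perturbations, toy dose engine, full case bundles |

## CLI

```sh
# generate a synthetic case on disk (NIfTI + CSV + YAML)
planqa simulate --seed 17 --out case_dir/

# full per-case QA; exit code 0 iff overall pass
planqa run --case case_dir/case.yaml --out report.json --text

# individual stages
planqa resample --ref ref_dose.nii --eval eval_dose.nii --spacing 1.5
planqa mask --ct ct.nii --margin-mm 20 --out mask.nii
planqa gamma --ref r.nii --eval e.nii --mask mask.nii --dd 2 --dta 2 --stats stats.json
planqa fiducials --mri fid_mri.csv --ct fid_ct.csv --tol-mm 1.0

# aggregate per-case reports
planqa cohort report1.json report2.json --out cohort.csv
```

Configuration (tolerances, gamma criteria, manual checklist flags) is YAML:

```yaml
tolerances:
  iso_dose_pct: 2.0
  gamma_pass_pct: 90.0
  fiducial_tol_mm: 1.0
  skin_margin_mm: 20.0
  resample_mm: 1.5
criteria:
  - {dose_diff_pct: 2, dta_mm: 2}
manual_flags:
  Image transfer: true
```

## Conventions

- All geometry is DICOM-style **LPS, millimetres, world coordinates**;
  grids are axis-aligned; a grid's `origin` is the **center** of voxel
  (0, 0, 0).
- Doses are Gy; the reference dose is always the verification-CT
  recalculation.
- Gamma uses global normalization (max reference dose in the mask) by
  default; `normalization="local"` is available.
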