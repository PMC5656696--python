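# centiloid

Standardization of amyloid-PET quantification on the Centiloid (CL) scale:
image-space SUVR over standard MNI-152 volumes of interest, level-1 pipeline
validation, level-2 inter-tracer calibration, and young-normal cohort QC —
with synthetic phantoms and cohorts so every stage runs without clinical data.

## Who this is for

Groups quantifying amyloid PET who need their tracer's standardized uptake
value ratio (SUVR) expressed in Centiloid units — the 100-point scale anchored
at 0 (mean of young, amyloid-free controls) and 100 (mean of mild Alzheimer's
disease) for ¹¹C-PiB with the whole cerebellum as reference — and who need the
bookkeeping around it: gate checks, equation composition, and QC reports.

## The method

SUVR is the ratio of mean uptake in the standard cortical VOI to mean uptake
in the whole-cerebellum reference VOI, both applied to spatially normalized
(MNI-152) volumes. For PiB the published conversion is

    CL = 93.7 × SUVR_PiB − 94.6

Calibrating a second tracer such as ¹⁸F-florbetaben (FBB) has two levels:

* **Level 1** — confirm the local pipeline reproduces reference CL values on
  the standard PiB set: R² > 0.98, slope within [0.98, 1.02], intercept
  within [−2, +2] CL.
* **Level 2** — regress the tracer's SUVR on paired PiB SUVR
  (gate R² > 0.70), invert the fit to the "calculated PiB SUVR"
  ^PiB-Calc^SUVR = (SUVR_FBB − b)/m, and compose with the standard PiB map to
  obtain a direct equation. For the relation
  SUVR_FBB = 0.61 × SUVR_PiB + 0.39 the composition gives
  CL = 153.6 × SUVR_FBB − 154.5, matching the published
  CL = 153.4 × SUVR_FBB − 154.9 within rounding of the printed coefficients.

QC over young controls reports per-tracer CL mean/SD, the SD ratio
(relative measurement noise; 6.81/3.48 ≈ 1.96 for FBB vs PiB), and
2·SD upper limits of the amyloid-negative range (7 CL PiB, 14 CL FBB).

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_validate_level1.py
python analysis/03_calibrate_fbb.py
python analysis/04_cohort_qc.py
```

The drivers simulate a 35-subject paired PiB/FBB cohort (10 young controls,
6 elderly controls, 9 MCI, 8 AD, 2 FTD), validate the image pipeline on
phantom volumes, and calibrate FBB. Output from a run:

```
slope 1.0000, intercept -0.002 CL, R^2 1.00000
pass_overall: True
---
fitted relation:   SUVR_FBB = 0.61 x SUVR_PiB + 0.39 (R^2 = 0.987, n = 35)
gate R^2 > 0.70:   pass
direct CL map:     CL = 153.0 x SUVR_FBB - 153.9
published-composed: CL = 153.6 x SUVR_FBB - 154.5
```

The level-1 block shows the phantom pipeline passing all three gates. The
level-2 block shows the fitted inter-tracer relation recovering the
generating slope/intercept, and the direct CL map it implies; the last line
is the same composition evaluated at the exactly published coefficients.
Tables and JSON reports land in `results/`.

The same steps are available as a CLI over NIfTI/CSV inputs:

```bash
centiloid suvr pet.nii.gz cortex.nii.gz cerebellum.nii.gz \
    --subject-id S01 --tracer FBB --out suvr.csv
centiloid calibrate pairs.csv --out report.json
centiloid validate computed.csv reference.csv
centiloid simulate --seed 7 --out-dir sim/
centiloid cohort-stats pairs.csv
```

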