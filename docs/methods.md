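# Methods

## Model

All scale arithmetic rests on one object: an affine map `y = m·x + b`
between named scales (`SUVR_FBB`, `SUVR_PiB`, `CL`). The standard PiB
conversion `CL = 93.7·SUVR_PiB − 94.6` is a package constant. A tracer
calibration is an ordinary-least-squares fit of the tracer's SUVR on paired
PiB SUVR (the orientation in which such relations are conventionally
reported), inverted to the calculated-PiB-SUVR map and composed with the
standard map. Compositions always use full-precision fitted coefficients;
published equations are treated as rounded views, which is why the
composition of the published relation (0.61, 0.39) gives 153.607/−154.507
rather than the printed 153.4/−154.9 — the residual is entirely rounding of
the printed inputs.

OLS rather than Deming/orthogonal regression is the default because the
reported relation is an OLS-style fit; an errors-in-variables treatment
would change the slope when PiB measurement noise is material. R² is the
squared Pearson correlation; the residual SD uses an n−2 denominator.

## Image-space statistics

SUVR is the ratio of region means (not the mean of voxelwise ratios): mean
uptake over the binary view of the cortical VOI divided by mean uptake over
the whole-cerebellum VOI. For a fixed reference mean the two conventions
coincide; ratio-of-means is the recorded choice. Masks are stored with
continuous weights but statistics use the binary view at a configurable
threshold (default 0.5), since the standard VOIs are distributed as masks
and no voxel-weighting rule exists. Non-finite voxels are excluded from
means and counted, never zero-filled (zero-filling biases SUVR downward).
Region SDs use the population (ddof = 0) denominator so a single-voxel
region is well defined; cohort CL SDs use the sample (n−1) denominator.

Grid mismatch between an image and a mask is a hard error: this package
never resamples, because silent interpolation changes region means. Affines
must agree elementwise within 1e-4 (absolute, mm-scale units) and dims
exactly. Voxel values are treated as unitless activity; SUVR is invariant
under global intensity scaling, so no dose or body-weight normalization is
applied. Partial volume correction is deliberately not performed.

## Gates and thresholds

* Level 1 (pipeline validation, computed CL regressed on reference CL):
  R² > 0.98 strict, slope in [0.98, 1.02] and intercept in [−2, +2] CL both
  inclusive. A 1e-9 absolute guard keeps exactly-on-boundary fits from
  failing on floating round-off.
* Level 2 (inter-tracer fit): R² > 0.70 strict. A gate failure produces a
  full report with `pass_gate = false` rather than an exception, so QC
  output remains inspectable.
* Upper normal limit: `mean + k·SD` of young-normal CL with k = 2 by
  default, rounded to integer CL (thresholds are conventionally reported as
  integers); the k·SD-only variant is exposed as well because the two
  coincide only when the young-normal mean is ≈ 0, which the CL scale
  guarantees by construction but a finite sample does not.

## Synthetic data

The phantom is a three-region block layout on a 2 mm grid (default
24³ voxels): a hollow cortical shell in the upper half, a solid cerebellar
block in the lower quarter, background elsewhere, with additive Gaussian
voxel noise. It emulates exactly what the SUVR engine consumes — prescribed
region means on a shared grid — and nothing else: no anatomy, no scanner
point-spread function, no reconstruction artefacts, no partial-volume
effects. Passing phantom tests therefore demonstrates the correctness of
the region statistics and scale math, not robustness to real-scan
confounds such as misregistration or atrophy.

The cohort simulator draws a true PiB SUVR per subject from its clinical
group's normal distribution, maps it through a linear inter-tracer relation
(default slope 0.61, intercept 0.39), and adds independent Gaussian
measurement noise to each tracer's observed SUVR. Defaults, chosen once:

* Group layout: 10 young controls, 6 elderly controls, 9 MCI, 8 mild AD,
  2 FTD (35 subjects), mirroring a head-to-head calibration cohort.
* Group means on the CL scale — young 0, elderly controls 20, MCI 50,
  AD 100, FTD 5 — mapped to SUVR through the inverse standard PiB map
  (young ≈ 1.010, AD ≈ 2.077 SUVR). These anchor the scale's defining
  points; the intermediate values are generator conventions.
* Within-group biological SDs (CL): 3 / 20 / 25–30 / 25 / 5. The young
  value is set so that, combined with measurement noise, the observed
  young-normal totals reproduce the published SDs; the clinical-group
  values span the heterogeneity typical of amyloid cohorts and are
  conventions, not measured quantities.
* Measurement noise: PiB √(3.48² − 3²) ≈ 1.76 CL and tracer
  √(6.81² − 3²) ≈ 6.11 CL (each divided by the respective CL-per-SUVR
  slope), so the default young-normal CL SD ratio is ≈ 1.96.

`tracer_noise_for_target_r2` solves in closed form for the tracer noise
giving a prescribed expected inter-tracer R² under the group layout
(ρ² = (mV)²/((V+σx²)(m²V+σy²)) with V the mixture variance of true PiB
SUVR), used by the parameter-recovery studies at R² = 0.96. Observed SUVRs
are floored at 0.05 so records stay physical under extreme noise; at the
default noise levels the floor is never hit.

All randomness flows through `numpy.random.default_rng(seed)`; a fixed seed
reproduces volumes and cohorts bit-identically.

## Numerical choices and degenerate inputs

Regression requires n ≥ 3 and non-constant x; map inversion requires a
nonzero slope; the reference region mean must be strictly positive; an
all-missing or all-zero mask is an error. NIfTI volumes are written as
float64 so write/read round-trips are bit-exact. 4D inputs are rejected
with instructions to pre-average frames (trailing singleton dimensions are
tolerated). Mask files coded on other scales (e.g. 0/255) are rescaled by
their maximum before clamping to [0, 1], so binary masks stay binary.

## Problem sizes

Default test and analysis sizes — 24³ phantoms, 35-subject cohorts, 100–500
replicate parameter-recovery studies — were chosen to match the study design
being emulated while keeping every check a matter of seconds.

## Limitations

* Spatial normalization, coregistration and segmentation are out of scope;
  inputs must already be on a common MNI-152 grid.
* The simulator's Gaussian noise and normal group distributions are
  analyzability choices; real SUVR distributions are right-skewed in mixed
  cohorts and noise can scale with uptake.
* Only linear inter-tracer calibrations are supported; the reference-region
  variant used in histopathology studies (cerebellar cortex) and
  histopathology-anchored thresholds are not implemented.
* Published young-normal CL means appear with inconsistent tracer pairing
  across report locations in the source literature (−1.08/−0.32 swapped);
  the SDs (6.81 FBB, 3.48 PiB) are consistent and are the only values this
  package's defaults depend on.
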