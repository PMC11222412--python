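# Methods

## Scope and design

`srstroke` implements a multimodal imaging pipeline for binary prediction
of infarct-volume trend (reversal vs. enlargement of the DWI lesion at
7–10-day follow-up) from baseline SWI and CT perfusion, together with a
synthetic cohort generator that stands in for patient images. The package
is a library first (importable API plus `examples/`), with a thin CLI for
shell use.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
CT/MR physics.

* **Grid.** Default 16×16×16 voxels at 1 mm isotropic spacing, 26 CTP
  frames at 1.5 s (the target acquisition's dynamic protocol). All spatial
  sizes are scaled down roughly 1/32 from clinical 512² slices so that a
  ~100-patient cohort simulates and processes in seconds; the peri-infarct
  dilation scales with it (2 px in-plane / 2.0 mm instead of the
  full-resolution 20 px / 2–3 mm convention, preserving the band-to-lesion
  ratio).
* **CTP.** Every voxel follows the Gaussian bolus model exactly, with
  per-voxel parameters drawn around gray-matter-like values: baseline
  35 ± 2 HU, amplitude 30 ± 3 HU, peak 12 ± 1 s, width 4 ± 0.4 s, plus
  additive frame noise (sd 2 HU, a typical low-dose CTP level). Lesion
  voxels (a sphere, default radius 3 vox) peak later — a patient-level
  delay drawn from N(2 s, 1 s) for reversal and N(6 s, 1 s) for
  enlargement (`ttp_delay_enlargement_s = 4`), with the 2-voxel band around
  the lesion receiving half the delay — and enhance less
  (`amplitude_reduction = 0.35`).
* **SWI.** Background 100 ± 5 intensity units; 3–6 dark random-walk
  polyline "veins" inside the peri-lesional band, with depth N(40, 8) for
  enlargement and 0.35·40 for reversal (`vein_contrast_enlargement = 40`).
* **Classes.** `class_balance` defaults to 18/33, the enlargement fraction
  of the 33-patient test cohort implied by the evaluated confusion
  matrices. Per-patient RNG streams are children of the cohort seed
  (`SeedSequence(seed, spawn_key=(i,))`), so cohorts are bit-reproducible
  element-wise and the label sequence is seed-independent.

What the simulator does **not** model: arterial input functions,
recirculation, beam hardening, motion, partial-volume effects, registration
error, or realistic lesion morphology. Passing tests therefore demonstrate
the pipeline's statistical machinery, not clinical performance; absolute
AUC values on synthetic cohorts are not comparable to patient studies.

## Perfusion fitting

A single vectorized Levenberg–Marquardt routine fits
`b + A·exp(−(t−t_p)²/(2σ²))` to every curve (the scalar and whole-map
paths share it, so they agree exactly). Initialization: baseline = mean of
the first 3 frames, amplitude = max − baseline, peak = argmax time,
width = half the above-half-maximum span floored at one frame interval.
Bounds: `A ≥ 0`, `σ ∈ [0.75 s, scan span]`. Convergence: relative cost
change below 1e−14 or step below 1e−10, at most 60 iterations; noiseless
in-model curves recover all four parameters to better than 1e−6, and under
sd-2 noise the fits match an independent `scipy.optimize.curve_fit` rerun.

A fit is **degenerate** (indices undefined, NaN in the maps) when the
amplitude falls below `max(3·robust residual sd, 0.5 HU)` — the absolute
floor guards the noiseless case, where a purely noise-scaled rule would
accept a zero bolus — or when the fitted peak lies outside the
scanned window. Perfusion indices are deliberately AIF-free and relative
(blood flow assumed uniform and stable over the scan); only intra-cohort
comparability is claimed. Indices are computed from the *fitted* curve,
not the raw samples.

## Radiomics

513 features per channel = 57 base features × (original + 8 wavelet
sub-bands). The 57 are 18 first-order statistics, 24 co-occurrence (GLCM)
statistics and 15 run-length (GLRLM) statistics. Conventions:

* Gray levels: 32-bin min–max quantization of in-mask intensities, making
  texture and histogram features invariant to intensity shifts.
* GLCM: symmetric, normalized, matrix-averaged over the 13 unique 3-D unit
  offsets; GLRLM over the same 13 directions. Toy-grid values are verified
  against exhaustive pair/run enumeration.
* Population (biased) variance throughout; entropies in bits.
* Degenerate (single-gray-level) regions fall back to fixed constants
  (entropy 0, uniformity 1, contrast 0, correlation 0, MCC-texture 1);
  no feature is ever NaN.
* Wavelet: single-level periodized `db4` (orthonormal 8-tap), sub-band
  ROIs by 2× nearest-neighbor downsampling, grown if fewer than 2 voxels
  survive. Non-finite voxels (unfitted map entries) are mean-imputed
  before the transform and excluded from the mask.

Feature normalization is a z-score using training-split statistics only;
zero-variance training columns are zeroed in both splits and recorded.

## Sparse models

Both L0 problems are solved by orthogonal matching pursuit with a sparsity
budget as the practical surrogate for the penalty weight (the penalty
parameters have no published values): selection budget = `n_select`
(default 20, capped at the sample count with a warning), classifier budget
= `min(10, dictionary columns)`, residual tolerance 1e−6. Atom choice is
by maximal absolute correlation normalized by column norm, with
least-squares refit of the active set each step; an exhaustive
support-enumeration solver (`brute_force_l0`, guarded to ≤ 15 columns)
serves as the testing oracle — greedy single-atom selection is provably
exact and is verified against it instance-by-instance.

Selection regresses the −1/+1-coded label vector on z-scored feature
columns. The SRC dictionary, however, is built from **sd-scaled,
uncentered** selected features: centering makes the two classes antipodal
around the origin, and a coder that selects atoms by absolute correlation
then reconstructs a test sample equally well from negated opposite-class
atoms, collapsing the class-residual contrast (measured: two-Gaussian
accuracy 0.52 antipodal vs 0.91 one-sided). Scaling without centering
keeps residuals comparable across features while preserving the one-sided
geometry of raw radiomics intensities. Dictionary columns are unit-norm;
fitting is non-parametric (no iteration).

Decision rule: minimum class-restricted residual, ties to the lowest class
index and flagged. The ROC score is the normalized residual margin
`(r_reversal − r_enlargement)/(r_reversal + r_enlargement)`, so larger
means enlargement. A k-nearest-residual variant
(`src_predict_kproximity`) is provided for sensitivity analyses; the
residual-argmin rule is primary.

## Evaluation

Positive class = enlargement. Rates are computed from integer counts;
zero-denominator rates return `None` rather than 0; `err = 1 − acc`
exactly; display rounding is 3-decimal round-half-even. AUC follows the
Mann–Whitney rank-sum convention with half credit for ties (verified
against O(n²) pair counting and scikit-learn). The F-score is standard F1
on the positive class. The normalized-rank cutoff maps scores to average
ranks divided by n and picks the level maximizing accuracy (ties to the
lowest level, equivalent to exhaustive threshold enumeration); pipeline
reports include both the argmin-residual metrics (primary) and the
best-level sweep of the evaluated scores.

## Pipeline

Train (66) and test (33) cohorts are independent simulations whose seeds
derive deterministically from the run seed; normalization and selection
are fit on the training cohort only. Features are extracted once for all
channels and modality views (SWI / CTP / SWI+CTP) are column subsets.
Artifacts (feature CSVs, model JSON, predictions CSV, metrics JSON, log)
carry the config hash and seed; identical config + seed reproduce
byte-identical metrics JSON.

## Problem sizes used in tests and the acceptance script

Cohort-level checks run 16³ grids with 66/33 cohorts (20 seeds in the test
suite, 5 in the acceptance script); fit-recovery checks use 26-frame
curves (50 noiseless, 200 noisy); solver checks 100 random 12×8
instances; classifier checks 50 seeds of 40/20 two-Gaussian splits. These
sizes were chosen so the whole suite completes in a few minutes on one
CPU while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Perfusion surrogates are relative; no deconvolution, MTT, or absolute
  quantification.
* The DWI segmenter is a thresholding stub; synthetic truth masks are the
  primary lesion source.
* The radiomics family reconstructs a standard 513-dimensional
  gray/texture/wavelet panel; it does not replicate any specific toolkit's
  feature definitions, and shape/morphology features are out of scope.
* The residual-argmin SRC rule is statistically inefficient on weakly
  separated isotropic point clouds (nearest-mean-style rules dominate
  there); it is used because it is the method under study.
* Confidence intervals and model-comparison tests are out of scope.
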