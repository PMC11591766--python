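# Methods

## Overview

`braintex` implements a slice-based texture-radiomics pipeline for staging
Alzheimer's disease from skull-stripped structural MRI. A 3D volume is reduced
to 24 fixed-position 2D slices (8 per anatomical plane), each slice is resized
to 156×156, min–max normalized to [0, 1] and quantized to 8 gray levels; a
non-symmetric gray-level co-occurrence matrix (GLCM) is built at four directed
offsets per slice, 22 scalar texture statistics are computed per GLCM, and the
resulting subjects × features matrices (2112 columns for three planes, 704 per
single plane) are z-scored column-wise, optionally filtered by incremental
F-score selection, and benchmarked with a grid of classifiers on a single
stratified 80/20 hold-out split. Because real staging cohorts are
access-restricted, the package ships a synthetic phantom generator that
reproduces the *structure* of such a cohort and provides positive and null
controls for the whole pipeline.

## Synthetic cohort

Each phantom is an ellipsoidal "brain" (semi-axes 0.9, 0.85, 0.9 of the half-
extents of a 91×109×91 voxel grid at 2 mm) whose interior is a uniform(0,1)
noise field blurred with a group-specific Gaussian sigma and rescaled to
[0.2, 1.0], minus a central ellipsoidal zero-intensity cavity, plus additive
Gaussian noise; the background outside the mask is exactly zero
(skull-stripped contract).

Two handles emulate disease progression monotonically across the CN → MCI →
AD groups:

| parameter | CN | MCI | AD | unit | role |
|---|---|---|---|---|---|
| `texture_smoothness` | 2.5 | 1.8 | 1.2 | voxels (blur σ) | finer, higher-contrast texture with disease |
| `noise_sd` | 0.02 | 0.04 | 0.06 | intensity | mild heteroscedasticity |
| `cavity_radius_frac` | 0.10 | 0.18 | 0.28 | fraction of brain semi-axes | ventricular-enlargement / atrophy analogue |

These defaults were chosen once so that binary group separation is
near-perfect — the positive control needs a recoverable effect — while
`effect_scale` interpolates all three maps toward the CN values (0 gives a
null cohort with identical groups; values in (0, 1) give a "hard mode").
Blur sigma *decreasing* with severity makes mean GLCM contrast strictly
increase CN → MCI → AD, which a property test verifies in expectation over
20 subjects per group.

Determinism: each subject's RNG stream is seeded by `(root_seed,
subject_counter)`, so identical configs are bit-identical and growing the
cohort never reshuffles earlier subjects.

What the phantom does **not** emulate: neuroanatomy (no tissue classes, no
hippocampus, no cortical folding), scanner physics, registration error, or
inter-subject anatomical variability beyond the texture/cavity handles.
Passing the recovery control therefore shows the pipeline can detect
texture/atrophy-like differences it was pointed at — not that it would reach
any particular accuracy on clinical data.

## Slicing and pre-processing

* Slice positions: 8 equally spaced fractional depths 0.15, 0.25, …, 0.85 of
  each axis, index = round(f·(dim−1)) — fixed, content-independent, and away
  from near-empty edge slices. For an axis of length 91 this gives indices
  14, 22, 31, 40, 49, 58, 68, 76 (half-integer depths resolve by the
  platform's round-half-to-even).
* Resize: bilinear (pixel-center aligned, edge-clamped, no anti-aliasing) to
  156×156; constants are preserved exactly, verified against a hand-written
  bilinear oracle.
* Normalization: (x − min)/(max − min) per slice; an all-constant slice maps
  to zeros rather than erroring, keeping the per-subject slice count total.
* Quantization: equal-width binning of [slice min, slice max] into 8 levels
  1…8 (the gray-limits convention of standard co-occurrence routines); the
  maximum maps to level 8, a constant slice to level 1.
* A `via_png` flag reproduces an 8-bit PNG intermediate (round through
  0–255); the default pipeline keeps the float grid in memory.

## Co-occurrence features

GLCMs are accumulated non-symmetrically (each offset is a directed neighbor
relation) at offsets (0,1), (−1,1), (−1,0), (−1,−1). Conventions that the
feature definitions leave open were fixed as follows and are isolated in one
module:

* all entropies use base-2 logs with 0·log 0 := 0 and no epsilon;
* the variance feature is centered on the symmetric GLCM mean
  μ = Σ ½(i+j)·p(i,j);
* sum variance is centered on sum average (the only self-contained choice
  expressible from the sum distribution itself);
* correlation is the standard normalized GLCM covariance; it is computed by
  two algebraically equivalent routes (`correlation1`, `correlation2`) whose
  agreement is itself a test;
* degenerate cases: correlations and IMC1 are 0 when σ_x·σ_y or max(HX, HY)
  vanish, so constant slices yield finite feature vectors.

Each GLCM is normalized per offset before feature computation; a slice yields
a 22×4 feature block. Correctness rests on dual-route tests: exact count
agreement with a brute-force double loop and ≤1e−10 feature agreement with a
literal loop transcription of the formulas, over 100 random slices, plus a
cross-check of the raw counts against `skimage.feature.graycomatrix`.

## Matrix assembly and scaling

Columns are ordered plane-major, then slice 0–7, then feature, then offset,
named `plane.slice.feature.offset`; the identity 22·4·8·|planes| is asserted
on every matrix. Pairwise comparison matrices are row-subsets of one full
matrix, so column meaning is constant across comparisons. The faithful
default z-scores each comparison matrix before splitting (mean 0, SD 1 with
n−1 denominator; zero-variance columns → 0); `split_safe_scaling=True`
refits the scaler on the training fold only, for a leakage-free variant.

## Feature selection

Per-column F-score: between-class scatter over summed within-class variances,
generalized from two to three classes by summing over the classes present.
Zero denominator gives +∞ when the class means differ (ranked first) and 0
otherwise; ties break by ascending column index for reproducibility.
Incremental subsets are nested prefixes of the ranking, sizes 2 … columns−1
(the upper end replicates the published sweep's bound); a stride parameter
thins the sweep for desk-scale runs but always includes the final size.

## Classification and metrics

17 distinct classifier configurations (scikit-learn plus LightGBM) form the
no-selection grid; the selection stage uses the seven that the published
report tables feature (LinSVC, OvsR, ExTreeC, LogRegCV, LogReg, BaggC,
DeTreeC), configurable. One global seed drives the split and every stochastic
learner. Evaluation is a single stratified 80/20 hold-out; the positive class
of a binary pair is its second-named group.

Metrics per cell: accuracy, precision, recall, specificity = TN/(TN+FP),
F1, Gmean = √(recall·specificity), and ROC AUC from continuous decision
scores where available (class-indicator fallback otherwise), reported as
percentages. Multi-class metrics are class-frequency-weighted one-vs-rest
values, under which weighted recall ≡ accuracy. A
`gmean_variant="precision-specificity"` option reproduces the alternative
convention some published tables follow. The best-k row in selection mode is
chosen by test-set accuracy (the published, optimistic protocol);
`select_k_by="nested"` instead picks k on an inner validation split of the
training fold.

## Controls and problem sizes

The built-in controls run at desk scale, chosen as follows:

* **positive control** — 60 CN + 60 AD phantoms at default effect sizes,
  three-plane matrix, F-score sweep with stride 64 and the LinSVC/ExTreeC
  pair; the best accuracy should be ≥ 90% (it is 100% in practice).
* **null control** — 60+60 phantoms with identical group parameters,
  logistic regression on the full feature set, 5 seeds. With a 24-subject
  test fold the per-seed accuracy is Binomial(24, ½)/24, so the 5-seed mean
  has SE ≈ 4.6 pp; the acceptance band 50% ± 3·SE ≈ [36.3%, 63.7%] was fixed
  from this calculation before the control was first run.

The analysis scripts use a quarter-scale cohort (42/59/26, preserving the
167/235/102 group proportions) and a thinned k-sweep; all bookkeeping
identities (2112/704 columns, 24 slices/subject, 12,096 slice images at 504
subjects) are recomputed at full cohort size, which costs only seconds to
minutes since they do not require the classifier sweep.

## Known limitations

* The hold-out protocol evaluates one random split; reported accuracies on
  small test folds are high-variance, and the best-k selection on the test
  fold is optimistic by construction (both replicated deliberately, with
  leakage-free options exposed).
* The phantom's texture effect is global and stationary; real disease effects
  are focal and anatomically structured.
* GLCM features are 2D and per-slice; no volumetric co-occurrence, run-length
  or wavelet features.
* `QuadraticDiscriminantAnalysis` and `GaussianProcessClassifier` are
  ill-conditioned when features ≫ subjects; they remain in the grid for
  completeness and their warnings are suppressed, not fixed.
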