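# Methods

This note documents the models, conventions and parameter choices of
`elastomics`, in the order data flows through the pipeline.

## Color conversion

**Luminance ("direct") conversion.** `to_gray_direct` computes
`0.2126 R + 0.7152 G + 0.0722 B` per pixel, evaluated as
`(2126 R + 7152 G + 722 B) / 10000`. The numerator is an exact integer
in float64, so achromatic pixels (R=G=B=v) map to exactly `v`, and the
conversion of any two exact metamers (colors whose integer numerators
are equal) is bit-identical. The result is kept at full float precision
for feature extraction; re-quantizing to 8 bits would add a second loss
on top of the projection itself. A separate export path
(`write_gray_image`) rounds half-up for PNG output.

**Channel decomposition.** `split_channels` copies the R, G and B
planes into three grayscale images; `recombine` stacks them back and is
an exact inverse (property-tested on random images). Files with an
alpha channel are rejected rather than silently flattened.

Clinical SWE frames often carry a grayscale B-mode underlay beneath the
color box; the package assumes single-pane, pre-registered color images
and makes no attempt to strip an underlay.

## ROIs

Lesion ROIs arrive either as closed polygons (JSON list of [row, col]
vertices) or as 0/255 PNG masks. Rasterization uses 0-based row-major
pixel coordinates: pixel (r, c) is foreground iff its center
(r + 0.5, c + 0.5) is inside the polygon by the even-odd ray-crossing
rule. This rule is deliberately simple enough to verify against a
brute-force point-in-polygon oracle, which the test suite does on
random (including self-intersecting) polygons. Degeneracy is defined as
vertex collinearity, not zero *signed* area — a self-intersecting
bow-tie has cancelling signed lobes but a genuine even-odd interior.

One `ROIMask` is propagated unchanged to the luminance image and all
three channel images, so feature differences between representations
are attributable to pixel intensities only.

## Feature bank

Families and their sizes are fixed: 19 first-order features, 10 GLCM
(Haralick) features, 5 GLRLM (Galloway) features, 4 mask-only shape
features. Conventions:

- **Discretization**: equal-width bins over the ROI's [min, max];
  constant ROIs map to bin 1. Default 32 bins (a common radiomics
  default).
- **First order**: population moments (ddof = 0); skewness
  `m3 / m2^1.5` and non-excess kurtosis `m4 / m2²`, both defined as 0
  for constant input; entropy in bits of the discretized histogram;
  energy is the sum of squared intensities, RMS the root of their mean.
- **GLCM**: symmetric accumulation over four unit directions
  (0°, 45°, 90°, 135°) scaled by an integer distance, matrices
  normalized to sum 1, features averaged over directions by default
  (Haralick convention). Correlation of a zero-variance matrix is
  defined as 1. ROIs of fewer than 2 pixels raise an error.
- **GLRLM**: maximal runs of equal discretized level along each of the
  four directions; a masked-out pixel breaks the run. Features averaged
  over directions by default. Run counts conserve pixels
  (Σ length·count = ROI size) by construction.
- **Shape**: area in pixels; perimeter as the count of exposed pixel
  edges; circularity `4πA/P²`; axis ratio `sqrt(λ1/λ2)` of the
  pixel-coordinate covariance eigenvalues with the single-pixel spread
  1/12 added to each, so line-like masks stay finite. Shape features
  depend only on the mask and are emitted once per lesion (never per
  channel): triplicating them would create exactly collinear columns.
- **Filters**: optional Laplacian-of-Gaussian at configurable sigmas
  (scipy `gaussian_laplace`, reflect boundary) and the four level-1
  stationary (undecimated) Haar wavelet subbands, computed at full
  image size so the same ROI mask applies (odd image sides are
  reflect-padded to even for the transform and cropped back).

The per-image feature count is a pure function of the configuration
(`FeatureBankConfig.size`). Three presets:

- `minimal` — first-order only (19 features), for fast end-to-end runs;
- `default` — first-order + GLCM + GLRLM + shape on the original image
  (38 per image, 106 for three channels);
- `paper_size` — a large bank representative of high-throughput
  ultrasomics platforms: 14 filter images (original, LoG σ = 0.5…4.5 in
  steps of 0.5, four wavelet subbands) × [19 first-order + GLCM emitted
  per direction over a {8,16,32}-bins × {1,2,3}-distance grid (360) +
  direction-averaged GLRLM over nine bin counts
  {8,12,16,24,32,48,64,96,128} (45)] = 5,936 intensity features per
  image, hence exactly 17,808 over three channels. In this preset GLCM
  features are emitted per direction rather than averaged (the grid is
  what makes a five-figure bank; direction-averaging remains the
  default everywhere else), and shape features are disabled so the
  three-channel count is exactly three times the single-image count.

The three-times law — `|extract_rgb3| = 3 × |extract_direct|` over
intensity features — holds for every configuration.

## Synthetic elastogram cohorts

The generator emulates what downstream stages actually consume: a
color-coded stiffness display with a labelled lesion, not acoustics. It
does **not** model shear-wave physics, speckle, acquisition artifacts,
operator variability or the B-mode underlay, so passing tests show the
pipeline's statistical machinery works — not that any particular
clinical performance would be attained.

- Background: mean 8 kPa (healthy liver parenchyma), marginal sd
  1.5 kPa, spatially correlated noise (Gaussian-smoothed white noise,
  blur radius 3 px, rescaled to the stated marginal sd).
- Lesion: one ellipse per image, semi-axes uniform in 8–18 px,
  orientation uniform, fully inside the frame; per-lesion mean
  stiffness drawn per class (benign 30 ± 6 kPa, malignant 70 ± 10 kPa
  between lesions), i.i.d. pixel noise within the lesion (sd 5 / 8 kPa)
  so the ROI sample mean obeys the usual sd/√n standard error.
- Colormap: piecewise-linear through dark blue (0, 0, 139) at vmin = 0
  kPa, green (0, 255, 0) at the midpoint, red (255, 0, 0) at
  vmax = 150 kPa, the qualitative palette of clinical SWE displays;
  channels rounded half-up to 8 bits. Stiffness outside the range is
  clipped.
- The ROI mask is the exact lesion ellipse — segmentation error is out
  of scope.

**Metameric mode** replaces the lesion's colormap colors with
class-specific base colors that are *exact* metamers of the luminance
formula: (84, 110, 118) for benign and (50, 130, 20) for malignant
differ by twice the integer null vector (17, −10, 49) of
(2126, 7152, 722), so both have luminance 105.05 exactly. Per-pixel
texture is integer G jitter (sd 3, identical in both classes — it
shifts luminance identically) plus a fair-coin step along the same null
vector (changes color, provably never luminance). The lesion's
luminance image therefore has an identical distribution — down to the
attainable value lattice — in both classes, while the R channel alone
separates the class means by 34 levels. An approximate isoline (e.g.
(50, G, 0) vs (0, G, 147), gray 10.630 vs 10.613) is not sufficient
here: with full-precision luminance kept for feature extraction, a
0.017 offset puts the classes on disjoint value lattices that
order-statistic features (median, min, max) expose, and a random forest
will memorize them. Exactness is what makes "information destroyed by
luminance conversion" a theorem rather than an approximation in this
generator.

Everything is a deterministic function of (config, seed): per-image
RNGs are spawned from one `SeedSequence`, and class labels are
interleaved in a fixed order so neither class is confounded with
generation order.

## Modelling

Pipeline order: **split → SMOTE (train only) → LASSO → classifier**,
with standardization fitted on the training side wherever distances or
penalties need it. Oversampling strictly inside the training cohort
prevents synthetic samples from leaking into validation.

- **Split**: stratified 1:1 random split (scikit-learn), seed recorded.
  A 130-lesion cohort with 90 malignant / 40 benign yields 65 training
  lesions with 45/20.
- **SMOTE**: each synthetic sample is `x + u(x′ − x)`, `u ~ U(0,1)`,
  with `x′` one of the k = 5 nearest minority neighbours by Euclidean
  distance on standardized features; interpolation happens in the
  original feature space; majority rows pass through untouched; k is
  truncated with a warning when the minority class is smaller than
  k + 1. A 45/20 training set becomes 90 balanced.
- **LASSO**: L1-penalized logistic regression (liblinear) over a
  descending λ grid (30 points, three decades down from the data-driven
  λ_max at which the standardized problem first goes all-zero), λ
  chosen by 5-fold stratified cross-validated deviance with the
  one-standard-error rule. Constant columns are dropped and exact
  duplicate columns collapsed to the lowest index before fitting — this
  makes the duplicate tie-break deterministic instead of relying on the
  solver's behaviour on collinear columns, and it is what makes the two
  pipeline arms provably identical on achromatic input. If the 1-SE λ
  selects nothing, the minimum-deviance λ is used; if selection is
  still empty (pure-noise features), the pipeline falls back to all
  features and lets the classifier see an uninformative table.
- **Classifiers** (all seeded): random forest with 500 trees; RBF SVM
  (C = 1, scale gamma); AdaBoost with 100 depth-1 stumps; unpenalized
  logistic regression. SVM and AdaBoost margins are mapped to [0, 1] by
  Platt-style sigmoid calibration fitted on training folds, so all four
  models emit comparable risk scores.
- **Operating cutoff**: Youden-optimal (max sensitivity + specificity −
  1) over midpoints of consecutive distinct scores, ties broken toward
  the lower cutoff, degenerate all-equal scores falling back to 0.5
  with a warning. Cutoffs are chosen on the raw (pre-SMOTE) training
  scores: the oversampled set has artificial prevalence, and the
  operating point should reflect the cohort as observed.

## Evaluation

- **AUC / DeLong**: AUC via the Mann–Whitney placement formulation
  (equal to trapezoidal ROC area, ties counted one half); DeLong
  variance from the sample covariances of per-observation placement
  values; paired test for two models scored on the same lesions.
  Verified in the test suite against exhaustive pair counting and
  against frozen values from the R package pROC.
- **Confusion metrics**: score ≥ cutoff ⇒ predicted malignant;
  confidence intervals are exact Clopper–Pearson binomial intervals.
  This deliberately diverges from normal-approximation (Wald)
  intervals, which can exceed 1 for proportions near the boundary —
  exact intervals cannot leave [0, 1].
- **NRI**: two-category variant; each model classifies at its own
  operating cutoff; NRI⁺ = net fraction of malignant lesions moved to
  predicted-malignant, NRI⁻ = net fraction of benign lesions moved to
  predicted-benign, total = exact sum. z uses the standard asymptotic
  variance (sum of the two components' binomial-difference variances
  `(p_up + p_down − (p_up − p_down)²)/n`). A continuous (cutoff-free)
  NRI is not currently offered.
- **Brier / calibration**: mean squared error of the score against the
  0/1 outcome; reliability diagram over 10 equal-width bins on [0, 1]
  with empty bins omitted.
- **Decision curves**: net benefit `TP/n − FP/n · pt/(1 − pt)` on a
  default grid 0.01–0.99 (step 0.01; pt = 1 is excluded because its
  odds weight diverges), against treat-all and treat-none.

## Problem sizes and determinism

The shipped experiments use 128 × 128 px images, 130-lesion cohorts and
the `default` (38-feature) bank for end-to-end runs; the `paper_size`
bank is exercised on single images, where one direct + three-channel
extraction takes a few seconds. All child seeds (cohort, split, SMOTE,
LASSO folds, per-classifier) derive from one master seed via
`SeedSequence` and are recorded in the run manifest; two runs with the
same manifest agree exactly, including liblinear's internal shuffling,
which is explicitly seeded.

## Known limitations

- The synthetic generator's colormap and stiffness statistics are
  plausible but vendor-agnostic; absolute feature values from synthetic
  images are not comparable to clinical ones.
- The metameric experiment demonstrates a *mechanism* (information
  destroyed by luminance projection, recovered by channel
  decomposition) under conditions designed to isolate it; real color
  images mix metameric and luminance-visible contrast, so the size of
  the effect in practice is an empirical question this package cannot
  answer.
- Whether a clinical pipeline should round direct-converted gray to 8
  bits before feature extraction is a genuine degree of freedom;
  this package keeps full precision and documents it.
- No automatic segmentation, no multi-reader ROI agreement analysis,
  no deep-learning classifiers, no hyperparameter search.
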