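# Methods

This note documents the models, parameter choices and numerical
conventions behind `texent`, and what the synthetic cohort does and
does not establish.

## Pipeline

Each 8-bit grayscale ROI passes through: (1) optional filtration —
*normalize* (zero mean, unit population variance) or *median* (3×3
window, replicate-padded border); (2) feature extraction — 90
statistical features and/or 25 two-dimensional multiscale entropy
features; (3) per-feature two-group statistics; (4) standardization and
random-forest importance selection (top 25); (5) classification with
fixed-hyperparameter kNN / SVM / LR under patient-grouped stratified
5-fold cross-validation. Every random element is seeded; identical
configurations produce byte-identical artifacts.

## Two-dimensional multiscale entropy

Coarse-graining at scale *s* replaces the image by the means of its
non-overlapping *s*×*s* blocks (trailing pixels dropped). The matching
tolerance *r* = `r_factor` · SD is computed **once from the scale-1
image** and held fixed across scales, the standard multiscale
convention — otherwise scale-wise renormalization absorbs exactly the
amplitude decay the profile is supposed to measure.

Defaults, exposed in `EntropyParams` and recorded in run manifests:

| parameter | default | role |
|---|---|---|
| `m_match` | 1 | template side for SampEn2D / FuzzEn2D |
| `m_pattern` | 2 | template side for PermEn2D / DispEn2D / DistEn2D |
| `r_factor` | 0.2 | tolerance multiplier on the scale-1 SD |
| `fuzzy_n` | 2 | fuzzy membership exponent |
| `n_classes` | 4 | dispersion classes (normal-CDF mapping) |
| `n_bins` | 64 | distance-histogram bins for DistEn2D |
| `scales` | 1…5 | coarse-graining factors |

**Why two template sizes.** The window-matching measures compare
*m*×*m* windows pixel-by-pixel within *r*. The probability that two
windows agree at every pixel falls geometrically with the window area:
on an i.i.d.-valued 32×32 image with *r* = 0.2·SD, a 3×3 window match
has probability ≈ 10⁻⁹, so with *m* = 2 the conditional match count *A*
is almost surely zero and SampEn2D is undefined on precisely the
irregular images the measure is meant to rank. With *m* = 1 (windows
1×1 vs 2×2) both counts stay populated across the full
regularity range. The pattern-based measures have the opposite
degeneracy — a 1×1 ordinal pattern is trivial — so they default to
*m* = 2 (24 ordinal patterns, 256 dispersion patterns, which even
small ROIs can populate). Both sizes are configurable.

**Conventions.** Chebyshev (max-abs) window distance everywhere;
self-matches excluded; pairs counted once (the A/B ratio is unchanged
by the ordered/unordered factor 2). SampEn2D/FuzzEn2D windows for sizes
*m* and *m*+1 are taken at the common set of top-left positions, so the
ratio is a genuine conditional probability. PermEn2D breaks rank ties
stably (earlier index wins), making a constant image a single pattern.
DispEn2D maps pixels through the normal CDF with the image's own
mean/SD, then rounds `c·y + 0.5` into classes 1..c; a constant image
(zero SD) maps every pixel to the middle class. DistEn2D histograms all
unordered pairwise window distances into equal-width bins over [0,
max]; an all-zero distance set occupies one bin and scores 0.

**Undefined SampEn2D.** When *A* or *B* is zero the statistic is
undefined; the function returns NaN by default. Inside the feature
pipeline, NaN is replaced by the *measurement ceiling* ln *B* (or
ln of the pair count if even *B* = 0) — the largest value one
conditional match could have produced. Replacing it by 0 (the generic
missing-value policy used for the statistical features) would equate
"too irregular to measure" with "perfectly regular" and invert the
class ordering, so the ceiling is used instead; it keeps feature tables
finite and order-faithful.

## Statistical texture features

Quantization is equal-width into L = 32 levels over the ROI's own
min–max (constant image → level 1); fixed level count keeps matrices
comparable across ROIs. GLCM: distance-1 offsets in the four unique 2D
directions, symmetrized, normalized, features averaged over directions
(not merged). GLRLM: the same four directions, averaged. GLDM: 8-connected
dependence with α = 0 (exact level match). GLSZM: 8-connected zones.
NGTDM: in-bounds 8-neighbor means. The per-group feature lists (17 FOS,
22 GLCM, 14 GLDM, 16 GLRLM, 16 GLSZM, 5 NGTDM) follow the standard
radiomics definitions and are frozen as the package's contract — every
group emits exactly its count on any valid input.

NaN policy: features undefined on degenerate input (skewness/kurtosis
and GLCM correlation at zero variance) are set to 0 with a logged
warning; NGTDM coarseness of a constant image is capped at 10⁶.
Direction-averaged and direction-free groups are invariant under image
transposition; this is tested.

## Group statistics

Each feature is compared between classes with a two-sided test routed
by per-group Shapiro–Wilk (parametric only if **both** groups pass at
p > 0.05; a zero-variance sample routes nonparametric). The parametric
branch is the pooled-variance Student t-test (Welch available via the
route argument); the nonparametric branch is the Mann–Whitney U test
(exact for small untied samples). Stars: p < 0.05 `*`, < 0.01 `**`,
< 0.001 `+`, < 0.0001 `++`, strict upper bounds applied smallest-first.
No multiple-testing correction by default, with Benjamini–Hochberg as
an option. Coefficient of variation = sample SD (n−1) / mean; undefined
at zero mean.

## Selection and classification

Standardization uses the population-SD convention; constant columns are
flagged and map to zeros. Selection fits a 100-tree random forest
(seed 42) and keeps the k = 25 features with the highest Gini
importance. Forests are column-order sensitive, so the selector
re-orders columns canonically (sorted by name) before fitting, making
the selected set independent of input column order; ties at the k-th
rank are broken by a seeded shuffle recorded in the result.

By default (**leakage-safe mode**) standardization and selection are
refitted inside each CV training fold. **Paper mode** fits them once on
the full table before splitting — the order of operations some
protocols describe — and is provided, labeled, for comparison; it leaks
test-fold information into the selection and should be expected to bias
metrics upward.

Cross-validation splits *patients*, never images, stratifying class
proportions at the patient level (each patient has one unambiguous
class). The positive class is the irregular (SCC-like) one. kNN scores
for AUC are neighbor-vote fractions; SVM scores are decision-function
values; LR scores are probabilities. AUC is computed by pair-counting
(ties half), which equals trapezoidal integration over thresholds.
Zero-denominator metrics return 0 with a flag rather than raising
mid-experiment.

## Synthetic cohort

The generator emulates the *statistical* structure the analysis
assumes, not imaging physics:

* **regular class** — Gaussian white noise convolved with an isotropic
  Gaussian kernel (`corr_len_regular` = 18 px), amplitude 25 % of the
  intensity span, fading as the correlation length approaches the image
  size, plus a small noise floor (SD 6);
* **irregular class** — weak smooth background (10 % of span,
  correlation 8 px) plus i.i.d. Gaussian noise (SD 45);
* **patient structure** — images of one patient share a latent smooth
  field (weight 0.5) and patient-level lognormal jitter (σ = 0.3) on
  the class noise/smoothness parameter, so within-patient correlation
  of entropy features is real and grouped CV is meaningfully different
  from image-level CV;
* **injected corruption** — Gaussian noise (SD 4) and salt-and-pepper
  replacement (fraction 0.02), giving both filtrations something to do;
* **cohort layout** — 12 regular vs 19 irregular patients, 5 images
  each, mirroring a realistic imbalanced clinical cohort.

The `strong` preset was calibrated once so that the irregular class
exceeds the regular class in mean SampEn2D/FuzzEn2D/DispEn2D at *every*
scale (coarse-graining decorrelates a smooth field, so too short a
correlation length loses the ordering at scale 5 — hence 18 px, not
shorter) and so that both classes show patient-level clustering of
SampEn2D. The `weak` preset (regular: correlation 12 px + noise 30;
irregular: noise 45) overlaps the classes; `null` draws both classes
from identical parameters. Grouped-CV accuracy rises monotonically
along null → weak → strong; this end-to-end dial recovery is tested.
DistEn2D is *not* ordered by this dial — on smooth fields the window-
distance histogram is broad — and is deliberately excluded from the
ordering checks.

**What passing tests show — and don't.** The synthetic classes are
stationary Gaussian-derived fields; real tumor ROIs have anatomy,
intensity non-stationarity, acquisition artifacts and class overlap
that no preset reproduces. Perfect CV accuracy under the strong preset
verifies the pipeline's plumbing and leakage control, not clinical
discriminability; the published problem sits much closer to the weak
preset's regime.

## Problem sizes and determinism

The end-to-end acceptance study uses 64×64 ROIs (155 images per
cohort); the package default for generation remains 128×128. 64 px
keeps the O(N²) window-pair reductions (N ≈ 4000 windows at scale 1)
in the pdist fast path while preserving all five scales with ample
window counts; pairwise kernels switch to a blocked two-pass
accumulation above 5000 windows, so 128-px cohorts run in bounded
memory. All cohort, CV, selection and permutation seeds derive from a
single user seed; two identical runs produce byte-identical images,
manifests, feature CSVs and fold metrics (tested).

## Known limitations

* Entropy parameter defaults (m, r, c, B) are field conventions, not
  fitted values; results at other settings are not characterized.
* The 17/22/14/16/16/5 feature name lists pin one standard variant of
  each family; other radiomics toolkits differ in a few definitions
  (e.g. GLCM MCC is omitted here).
* `paper mode` deliberately reproduces a leaky order of operations and
  must not be used for reported metrics.
* The generator's irregularity dial moves all entropy families
  together; it cannot emulate textures where, say, only ordinal
  structure differs between classes.
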