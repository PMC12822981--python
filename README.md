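# texent

Entropy-based and statistical texture analysis of grayscale ROI images,
with patient-grouped cross-validated classification.

`texent` re-implements, as a tested and reusable pipeline, a radiomic
protocol for telling apart two tissue texture classes on small (e.g.
128×128) 8-bit regions of interest cut from medical images — the kind of
problem posed by discriminating histological subtypes of non-small cell
lung cancer (adenocarcinoma vs squamous cell carcinoma) on MRI, where
the two subtypes differ in how *irregular* the tumor texture is. It is
aimed at researchers who want the whole chain — filtration, feature
extraction, statistics, selection, evaluation — in one inspectable,
seedable package, exercised end-to-end on a synthetic cohort generator
so every stage is testable without access to clinical data.

## What it computes

**Two-dimensional multiscale entropy (25 features).** Five irregularity
measures — SampEn2D, FuzzEn2D, PermEn2D, DispEn2D, DistEn2D — each
evaluated at scale factors *s* = 1…5 after coarse-graining (non-
overlapping *s*×*s* block means). For sample entropy,

&nbsp;&nbsp;&nbsp;&nbsp;SampEn2D = −ln(*A*/*B*),

where *B* counts pairs of distinct *m*×*m* windows whose Chebyshev
distance is ≤ *r* = 0.2·SD(image), and *A* counts the same for the
(*m*+1)-sized windows at the same positions. Fuzzy entropy replaces the
hard threshold with the membership exp(−*d*ⁿ/*r*); permutation,
dispersion and distribution entropy are normalized Shannon entropies of
ordinal patterns, normal-CDF class patterns, and the histogram of
pairwise window distances, respectively. Regular/periodic textures
score low, irregular ones high.

**Statistical texture features (90).** 17 first-order statistics plus
73 gray-level-matrix features (GLCM 22, GLDM 14, GLRLM 16, GLSZM 16,
NGTDM 5) in their standard IBSI-conformant definitions, computed from
scratch on 32-level equal-width quantized ROIs.

**Statistics, selection, classification.** Per-feature two-group tests
(Shapiro–Wilk-routed t-test / Mann–Whitney U, α = 0.05, star-coded),
coefficients of variation; standardization + top-25 selection by
random-forest importance (100 trees, seed 42); kNN (k = 7), RBF-SVM
(C = 100, γ = 10⁻⁴) and logistic regression (C = 1, lbfgs) evaluated by
5-fold cross-validation that is **grouped and stratified by patient**:
all images of a patient stay in one fold, which is what keeps
within-patient correlation from inflating the reported accuracy,
precision, recall, F1 and AUC (mean ± SD over folds).

## Worked example

```python
import numpy as np
from texent import make_regular_roi, make_irregular_roi, multiscale_profile

reg = make_regular_roi(64, corr_len=18, seed=3)     # smooth, ADC-like
irr = make_irregular_roi(64, noise_sd=45, seed=3)   # noisy, SCC-like
for name, img in [("regular", reg), ("irregular", irr)]:
    prof = multiscale_profile(img, "SampEn2D")
    print(name, np.round(prof.values, 3))
```

prints

```
regular [0.497 1.154 1.699 2.168 2.495]
irregular [6.432 4.572 3.485 3.186 2.854]
```

— the irregular texture has the higher sample entropy at every scale,
and the gap narrows with *s* because block-averaging smooths white
noise faster than it destroys long-range structure. The same ordering
driven through the full pipeline is what the classifiers pick up.

The one-command pipeline (generate → filter → features → stats →
select → evaluate) runs from the shell:

```bash
texent run-all --preset strong --seed 42 --out-dir runs/demo
```

and writes the cohort (BMP + manifest CSV), per-image-type feature and
statistics CSVs, and the 3 image types × 3 feature sets × 3 classifiers
results grid with per-fold values.

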