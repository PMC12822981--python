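"""Two-group statistical comparison of feature distributions.

Each feature is compared between the two diagnostic classes with a
normality-routed two-sided test: if both class samples pass a
Shapiro–Wilk test (p > 0.05) a pooled-variance Student t-test is used,
otherwise a Mann–Whitney U test. Significance is star-coded the way the
comparison figures annotate it:

====================  =========
condition             star code
====================  =========
p < 0.0001            ``++``
p < 0.001             ``+``
p < 0.01              ``**``
p < 0.05              ``*``
otherwise             (empty)
====================  =========

No multiple-testing correction is applied by default; Benjamini–
Hochberg adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import METADATA_COLUMNS, feature_columns

__all__ = [
    "TestResult",
    "star_code",
    "normality_route",
    "compare_groups",
    "coefficient_of_variation",
    "significance_table",
]

STAR_THRESHOLDS = ((0.0001, "++"), (0.001, "+"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TestResult:
    feature: str
    test_name: str  # "t-test" or "mann-whitney"
    statistic: float
    p_value: float
    significant: bool
    star_code: str


def star_code(p: float) -> str:
    """Star annotation for a p-value (strict upper bounds, smallest first)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must be in [0, 1]")
    for threshold, code in STAR_THRESHOLDS:
        if p < threshold:
            return code
    return ""


def _clean_sample(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    return arr


def normality_route(a, b, alpha: float = 0.05) -> str:
    """``"parametric"`` iff both samples pass Shapiro–Wilk at p > alpha.

    A sample with zero variance cannot be normal and routes the pair to
    the nonparametric branch.
    """
    a, b = _clean_sample(a), _clean_sample(b)
    for sample in (a, b):
        if np.ptp(sample) == 0:
            return "nonparametric"
        if stats.shapiro(sample).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    feature: str = "",
    route: str | None = None,
) -> TestResult:
    """Two-sided comparison of two samples with normality routing.

    ``route`` forces ``"parametric"`` or ``"nonparametric"``; by default
    it is decided by :func:`normality_route`.
    """
    a, b = _clean_sample(a), _clean_sample(b)
    if route is None:
        route = normality_route(a, b, alpha)
    if route == "parametric":
        res = stats.ttest_ind(a, b, equal_var=True)
        test_name = "t-test"
    elif route == "nonparametric":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test_name = "mann-whitney"
    else:
        raise ValueError(f"unknown route {route!r}")
    p = float(res.pvalue)
    return TestResult(
        feature=feature,
        test_name=test_name,
        statistic=float(res.statistic),
        p_value=p,
        significant=p < alpha,
        star_code=star_code(p),
    )


def coefficient_of_variation(x) -> float:
    """Sample SD (n-1 denominator) divided by the mean."""
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least 2 observations")
    mean = float(arr.mean())
    if mean == 0.0:
        raise ZeroDivisionError("coefficient of variation undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def significance_table(
    table: pd.DataFrame,
    label_col: str = "class_label",
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-feature two-group comparison over a feature table.

    ``table`` must carry the class label column and feature columns
    (metadata columns are skipped). Returns one row per feature with the
    test used, statistic, (optionally BH-adjusted) p-value, star code
    and the per-class coefficients of variation.
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    labels = table[label_col]
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    a_mask = labels == classes[0]
    b_mask = labels == classes[1]
    if a_mask.sum() < 3 or b_mask.sum() < 3:
        raise ValueError("each class needs at least 3 samples")
    feats = [c for c in feature_columns(table) if c != label_col]
    rows = []
    for feat in feats:
        col = table[feat].to_numpy(dtype=float)
        a, b = col[a_mask.to_numpy()], col[b_mask.to_numpy()]
        result = compare_groups(a, b, alpha=alpha, feature=feat)
        cov = {}
        for cls, sample in ((classes[0], a), (classes[1], b)):
            try:
                cov[cls] = coefficient_of_variation(sample)
            except ZeroDivisionError:
                cov[cls] = float("nan")
        rows.append(
            {
                "feature": feat,
                "test": result.test_name,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "significant": result.significant,
                "star_code": result.star_code,
                f"cv_{classes[0]}": cov[classes[0]],
                f"cv_{classes[1]}": cov[classes[1]],
                f"mean_{classes[0]}": float(a.mean()),
                f"mean_{classes[1]}": float(b.mean()),
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        adjusted = stats.false_discovery_control(out["p_value"].to_numpy())
        out["p_value"] = adjusted
        out["significant"] = adjusted < alpha
        out["star_code"] = [star_code(p) for p in adjusted]
    return out
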