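"""Two-dimensional multiscale entropy measures.

This module implements, from scratch, five 2D irregularity measures used
in image texture analysis — sample entropy (SampEn2D), fuzzy entropy
(FuzzEn2D), permutation entropy (PermEn2D), dispersion entropy (DispEn2D)
and distribution entropy (DistEn2D) — together with the coarse-graining
step that extends each of them to multiple spatial scales.

All five measures share the same basic object: the set of ``m x m``
pixel windows of an image. SampEn2D and FuzzEn2D ask how often windows
that are similar at size ``m`` (within a tolerance ``r``, Chebyshev
distance) remain similar at size ``m+1``; regular or periodic images
keep their matches and score near zero, irregular images lose them and
score high. PermEn2D looks only at the rank order of pixels within each
window, DispEn2D at a coarse ``c``-class discretization of the pixel
values, and DistEn2D at the histogram of all pairwise window distances.
PermEn2D, DispEn2D and DistEn2D are normalized into ``[0, 1]``.

Multiscale profiles are obtained by block-averaging the image with a
scale factor ``s`` (non-overlapping ``s x s`` block means) before the
entropy computation; the tolerance ``r`` is fixed once from the scale-1
image so that values remain comparable across scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist
from scipy.special import ndtr
from sklearn.base import BaseEstimator, TransformerMixin

from .images import as_pixel_array

__all__ = [
    "EntropyParams",
    "EntropyProfile",
    "ENTROPY_METHODS",
    "coarse_grain",
    "sampen2d",
    "fuzzen2d",
    "permen2d",
    "dispen2d",
    "disten2d",
    "multiscale_profile",
    "EntropyFeatureExtractor",
]

ENTROPY_METHODS = ("SampEn2D", "FuzzEn2D", "PermEn2D", "DispEn2D", "DistEn2D")

# Above this many windows, pairwise reductions switch from scipy's pdist
# (which materializes the full condensed distance vector) to a blocked
# accumulation that never stores more than one block of distances.
_PDIST_MAX_WINDOWS = 5000
_BLOCK = 128


@dataclass(frozen=True)
class EntropyParams:
    """Parameters shared by the five entropy measures.

    Attributes
    ----------
    m_match : int
        Template side length of the window-matching methods (SampEn2D,
        FuzzEn2D): windows of ``m_match x m_match`` pixels are compared
        against their ``(m_match+1)``-sized extensions. Default 1: with
        larger templates the conditional match count is zero (SampEn2D
        undefined) on all but near-periodic images, because the
        probability that two windows agree pixel-wise within ``r``
        shrinks geometrically in the window area.
    m_pattern : int
        Template side length of the pattern-based methods (PermEn2D,
        DispEn2D, DistEn2D). Default 2 (a 1x1 ordinal pattern would be
        degenerate).
    r_factor : float
        Tolerance multiplier; the matching tolerance is
        ``r = r_factor * SD(scale-1 image)``, held fixed across scales.
    fuzzy_n : float
        Exponent of the exponential fuzzy membership function.
    n_classes : int
        Number of dispersion classes ``c`` for DispEn2D.
    n_bins : int
        Histogram bin count ``B`` for DistEn2D.
    scales : tuple of int
        Ordered coarse-graining factors (default 1..5).
    """

    m_match: int = 1
    m_pattern: int = 2
    r_factor: float = 0.2
    fuzzy_n: float = 2.0
    n_classes: int = 4
    n_bins: int = 64
    scales: tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if self.m_match < 1 or self.m_pattern < 1:
            raise ValueError("template sizes must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")
        if self.fuzzy_n <= 0:
            raise ValueError("fuzzy_n must be > 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        scales = tuple(int(s) for s in self.scales)
        if not scales or any(s < 1 for s in scales):
            raise ValueError("scales must be a nonempty list of positive ints")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", scales)

    def feature_names(self, methods: Sequence[str] = ENTROPY_METHODS) -> list[str]:
        return [f"{meth}_s{s}" for meth in methods for s in self.scales]


@dataclass(frozen=True)
class EntropyProfile:
    """One entropy value per scale for a single method."""

    method: str
    scales: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.method not in ENTROPY_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.values) != len(self.scales):
            raise ValueError("values and scales must have equal length")


class ImageTooSmallError(ValueError):
    """Raised when an image cannot host the requested template size."""


def coarse_grain(image, s: int) -> np.ndarray:
    """Block-average an image by scale factor ``s``.

    Each output pixel is the mean of a non-overlapping ``s x s`` block;
    trailing rows/columns that do not fill a block are dropped.
    """
    x = as_pixel_array(image)
    s = int(s)
    if s < 1:
        raise ValueError("scale factor must be >= 1")
    if s == 1:
        return x.copy()
    h, w = x.shape[0] // s, x.shape[1] // s
    if h < 1 or w < 1:
        raise ImageTooSmallError(f"image {x.shape} too small for scale {s}")
    return x[: h * s, : w * s].reshape(h, s, w, s).mean(axis=(1, 3))


def _windows(x: np.ndarray, m: int) -> np.ndarray:
    """All m x m windows flattened row-major: shape (n_windows, m*m)."""
    if x.shape[0] < m or x.shape[1] < m:
        raise ImageTooSmallError(f"image {x.shape} smaller than template {m}x{m}")
    v = sliding_window_view(x, (m, m))
    return v.reshape(-1, m * m)


def _matched_windows(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """m and (m+1) windows taken at the common set of top-left positions."""
    if x.shape[0] < m + 1 or x.shape[1] < m + 1:
        raise ImageTooSmallError(
            f"image {x.shape} smaller than template {m + 1}x{m + 1}"
        )
    big = sliding_window_view(x, (m + 1, m + 1))
    w_big = big.reshape(-1, (m + 1) * (m + 1))
    w_small = big[:, :, :m, :m].reshape(-1, m * m)
    return w_small, w_big


def _chebyshev_match_count(w: np.ndarray, r: float) -> int:
    """Number of unordered distinct window pairs with Chebyshev distance <= r."""
    n = w.shape[0]
    if n <= _PDIST_MAX_WINDOWS:
        return int(np.count_nonzero(pdist(w, "chebyshev") <= r))
    total = 0
    for i0 in range(0, n - 1, _BLOCK):
        blk = w[i0 : i0 + _BLOCK]
        d = np.abs(blk[:, None, :] - w[None, i0:, :]).max(axis=2)
        rows = np.arange(blk.shape[0])[:, None]
        cols = np.arange(d.shape[1])[None, :]
        total += int(np.count_nonzero((d <= r) & (cols > rows)))
    return total


def _fuzzy_similarity_sum(w: np.ndarray, r: float, n_exp: float) -> float:
    """Sum of exp(-d^n / r) over unordered distinct pairs of centered windows."""
    wc = w - w.mean(axis=1, keepdims=True)
    n = wc.shape[0]
    if n <= _PDIST_MAX_WINDOWS:
        d = pdist(wc, "chebyshev")
        return float(np.exp(-(d**n_exp) / r).sum())
    total = 0.0
    for i0 in range(0, n - 1, _BLOCK):
        blk = wc[i0 : i0 + _BLOCK]
        d = np.abs(blk[:, None, :] - wc[None, i0:, :]).max(axis=2)
        rows = np.arange(blk.shape[0])[:, None]
        cols = np.arange(d.shape[1])[None, :]
        mask = cols > rows
        total += float(np.exp(-(d[mask] ** n_exp) / r).sum())
    return total


def _chebyshev_distance_histogram(w: np.ndarray, bins: int) -> tuple[np.ndarray, int]:
    """Histogram of pairwise Chebyshev distances over unordered distinct pairs."""
    n = w.shape[0]
    if n <= _PDIST_MAX_WINDOWS:
        d = pdist(w, "chebyshev")
        dmax = float(d.max()) if d.size else 0.0
        if dmax == 0.0:
            counts = np.zeros(bins, dtype=np.int64)
            counts[0] = d.size
            return counts, int(d.size)
        counts, _ = np.histogram(d, bins=bins, range=(0.0, dmax))
        return counts.astype(np.int64), int(d.size)
    # blocked two-pass: global max first, then histogram per block
    dmax = 0.0
    n_pairs = n * (n - 1) // 2
    for i0 in range(0, n - 1, _BLOCK):
        blk = w[i0 : i0 + _BLOCK]
        d = np.abs(blk[:, None, :] - w[None, i0:, :]).max(axis=2)
        rows = np.arange(blk.shape[0])[:, None]
        cols = np.arange(d.shape[1])[None, :]
        dmax = max(dmax, float(d[cols > rows].max(initial=0.0)))
    counts = np.zeros(bins, dtype=np.int64)
    if dmax == 0.0:
        counts[0] = n_pairs
        return counts, n_pairs
    for i0 in range(0, n - 1, _BLOCK):
        blk = w[i0 : i0 + _BLOCK]
        d = np.abs(blk[:, None, :] - w[None, i0:, :]).max(axis=2)
        rows = np.arange(blk.shape[0])[:, None]
        cols = np.arange(d.shape[1])[None, :]
        c, _ = np.histogram(d[cols > rows], bins=bins, range=(0.0, dmax))
        counts += c.astype(np.int64)
    return counts, n_pairs


def sampen2d(image, m: int = 1, r: float = 0.2, undefined: str = "nan") -> float:
    """Two-dimensional sample entropy.

    Counts pairs of distinct ``m x m`` windows whose Chebyshev distance is
    at most ``r`` (count B), and the same for ``(m+1) x (m+1)`` windows at
    the same top-left positions (count A); returns ``-ln(A / B)``.

    When either count is zero the statistic is undefined. With
    ``undefined="nan"`` (default) this is flagged as NaN; with
    ``undefined="ceiling"`` the measurement ceiling is returned instead —
    ``ln(B)`` (the largest value a single conditional match could have
    produced), or ``ln(n_pairs)`` if even B is zero. The ceiling keeps
    feature tables finite without mistaking extreme irregularity for
    regularity.
    """
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    if undefined not in ("nan", "ceiling"):
        raise ValueError("undefined must be 'nan' or 'ceiling'")
    x = as_pixel_array(image)
    w_small, w_big = _matched_windows(x, int(m))
    b = _chebyshev_match_count(w_small, r)
    a = _chebyshev_match_count(w_big, r)
    if a == 0 or b == 0:
        if undefined == "nan":
            return float("nan")
        n = w_small.shape[0]
        n_pairs = max(n * (n - 1) // 2, 1)
        return float(math.log(b if b > 0 else n_pairs))
    return float(-math.log(a / b)) + 0.0


def fuzzen2d(image, m: int = 1, r: float = 0.2, n: float = 2.0) -> float:
    """Two-dimensional fuzzy entropy.

    Windows are mean-centered and compared through the exponential
    membership function ``exp(-d^n / r)`` with ``d`` the Chebyshev
    distance; returns ``-ln(phi_{m+1} / phi_m)`` where ``phi`` averages
    the membership over distinct window pairs at common positions.
    """
    if r <= 0:
        raise ValueError("tolerance r must be > 0 for the fuzzy membership")
    if n <= 0:
        raise ValueError("fuzzy exponent must be > 0")
    x = as_pixel_array(image)
    w_small, w_big = _matched_windows(x, int(m))
    n_pairs = w_small.shape[0] * (w_small.shape[0] - 1) // 2
    if n_pairs == 0:
        raise ImageTooSmallError("need at least 2 windows")
    phi_m = _fuzzy_similarity_sum(w_small, r, n) / n_pairs
    phi_m1 = _fuzzy_similarity_sum(w_big, r, n) / n_pairs
    return float(-math.log(phi_m1 / phi_m)) + 0.0


def permen2d(image, m: int = 2) -> float:
    """Two-dimensional permutation entropy, normalized to [0, 1].

    Every ``m x m`` window is flattened row-major and encoded by the
    permutation that sorts it (stable: ties broken by earlier index);
    returns the Shannon entropy (natural log) of the pattern frequencies
    divided by ``ln((m^2)!)``.
    """
    m = int(m)
    if m * m > 9:
        raise ValueError("m^2 must be <= 9 (factorial pattern space guard)")
    x = as_pixel_array(image)
    w = _windows(x, m)
    if m == 1:
        return 0.0  # single trivial pattern
    order = np.argsort(w, axis=1, kind="stable")
    _, counts = np.unique(order, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(m * m)) + 0.0


def _dispersion_classes(x: np.ndarray, c: int) -> np.ndarray:
    """Map pixels through the normal CDF into integer classes 1..c."""
    mu = float(x.mean())
    sd = float(x.std())
    if sd == 0.0:
        return np.full(x.shape, int(round((c + 1) / 2)), dtype=np.int64)
    y = ndtr((x - mu) / sd)
    z = np.round(c * y + 0.5).astype(np.int64)
    return np.clip(z, 1, c)


def dispen2d(image, m: int = 2, c: int = 4) -> float:
    """Two-dimensional dispersion entropy, normalized to [0, 1].

    Pixels are mapped through the normal CDF (location/scale from the
    image itself) into ``c`` classes; each ``m x m`` window of classes is
    a dispersion pattern; returns the Shannon entropy (natural log) of
    the pattern probabilities divided by ``ln(c^(m^2))``.
    """
    c = int(c)
    if c < 2:
        raise ValueError("number of classes c must be >= 2")
    x = as_pixel_array(image)
    classes = _dispersion_classes(x, c)
    w = _windows(classes.astype(float), int(m)).astype(np.int64)
    # encode each pattern as a base-c integer
    base = c ** np.arange(w.shape[1], dtype=np.int64)
    codes = (w - 1) @ base
    counts = np.bincount(codes)
    counts = counts[counts > 0]
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / (w.shape[1] * math.log(c)) + 0.0


def disten2d(image, m: int = 2, bins: int = 64) -> float:
    """Two-dimensional distribution entropy, normalized to [0, 1].

    Chebyshev distances of all unordered distinct ``m x m`` window pairs
    are histogrammed into ``bins`` equal-width bins over [0, max
    distance]; returns the Shannon entropy (log2) of the empirical bin
    probabilities divided by ``log2(bins)``.
    """
    bins = int(bins)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = as_pixel_array(image)
    w = _windows(x, int(m))
    if w.shape[0] < 2:
        raise ImageTooSmallError("need at least 2 windows")
    counts, n_pairs = _chebyshev_distance_histogram(w, bins)
    p = counts[counts > 0] / n_pairs
    h = float(-(p * np.log2(p)).sum())
    return h / math.log2(bins) + 0.0


def multiscale_profile(
    image,
    method: str,
    params: EntropyParams | None = None,
    undefined: str = "nan",
) -> EntropyProfile:
    """Entropy of the coarse-grained image at every scale in ``params.scales``.

    The tolerance ``r`` for SampEn2D/FuzzEn2D is fixed once from the
    standard deviation of the scale-1 image. A constant image yields 0 at
    every scale for every method (block means preserve constancy).
    ``undefined`` is forwarded to :func:`sampen2d`.
    """
    if params is None:
        params = EntropyParams()
    if method not in ENTROPY_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {ENTROPY_METHODS}")
    x = as_pixel_array(image)
    sd = float(x.std())
    r = params.r_factor * sd
    matching = method in ("SampEn2D", "FuzzEn2D")
    m = params.m_match if matching else params.m_pattern
    values = []
    for s in params.scales:
        try:
            cg = coarse_grain(x, s)
        except ImageTooSmallError as exc:
            raise ImageTooSmallError(f"scale {s}: {exc}") from exc
        min_dim = min(cg.shape)
        needed = m + 1 if matching else m
        if min_dim < needed:
            raise ImageTooSmallError(
                f"scale {s}: coarse-grained image {cg.shape} smaller than "
                f"required template {needed}x{needed}"
            )
        if sd == 0.0:
            values.append(0.0)
            continue
        if method == "SampEn2D":
            values.append(sampen2d(cg, m, r, undefined=undefined))
        elif method == "FuzzEn2D":
            values.append(fuzzen2d(cg, m, r, params.fuzzy_n))
        elif method == "PermEn2D":
            values.append(permen2d(cg, m))
        elif method == "DispEn2D":
            values.append(dispen2d(cg, m, params.n_classes))
        else:
            values.append(disten2d(cg, m, params.n_bins))
    return EntropyProfile(method=method, scales=params.scales, values=tuple(values))


class EntropyFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer computing the multiscale entropy feature block.

    ``transform`` maps a sequence of images (2D arrays or
    :class:`~texent.images.RoiImage`) to an ``(n_images, n_features)``
    array with one column per (method, scale) pair, named
    ``<method>_s<scale>``. With the default five methods and scales 1..5
    this is the 25-column entropy feature set.

    Parameters mirror :class:`EntropyParams`; the transformer is
    stateless (``fit`` only validates parameters), so it can sit inside a
    cross-validation pipeline at no extra cost.
    """

    def __init__(
        self,
        m_match: int = 1,
        m_pattern: int = 2,
        r_factor: float = 0.2,
        fuzzy_n: float = 2.0,
        n_classes: int = 4,
        n_bins: int = 64,
        scales: tuple[int, ...] = (1, 2, 3, 4, 5),
        methods: tuple[str, ...] = ENTROPY_METHODS,
    ) -> None:
        self.m_match = m_match
        self.m_pattern = m_pattern
        self.r_factor = r_factor
        self.fuzzy_n = fuzzy_n
        self.n_classes = n_classes
        self.n_bins = n_bins
        self.scales = scales
        self.methods = methods

    def _params(self) -> EntropyParams:
        return EntropyParams(
            m_match=self.m_match,
            m_pattern=self.m_pattern,
            r_factor=self.r_factor,
            fuzzy_n=self.fuzzy_n,
            n_classes=self.n_classes,
            n_bins=self.n_bins,
            scales=tuple(self.scales),
        )

    def fit(self, X: Iterable = (), y=None) -> "EntropyFeatureExtractor":
        params = self._params()
        for meth in self.methods:
            if meth not in ENTROPY_METHODS:
                raise ValueError(f"unknown entropy method {meth!r}")
        self.feature_names_out_ = np.asarray(
            params.feature_names(self.methods), dtype=object
        )
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        params = self._params()
        rows = []
        for image in X:
            row: list[float] = []
            for meth in self.methods:
                prof = multiscale_profile(image, meth, params, undefined="ceiling")
                row.extend(prof.values)
            rows.append(row)
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        return self.feature_names_out_
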