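"""First-order and gray-level-matrix texture features.

Implements the classical statistical radiomics feature set on 2D ROIs:

* **FOS** — 17 first-order statistics of the intensity distribution;
* **GLCM** — 22 features of the symmetrized, normalized gray-level
  co-occurrence matrix (distance-1 offsets, four unique 2D directions,
  per-direction features averaged);
* **GLDM** — 14 features of the gray-level dependence matrix
  (8-connected neighbors within ``alpha`` gray levels);
* **GLRLM** — 16 run-length features (four directions, averaged);
* **GLSZM** — 16 size-zone features (8-connected equal-level zones,
  direction-free);
* **NGTDM** — 5 neighborhood gray-tone difference features.

Formulas follow the standard (IBSI-conformant) definitions used across
the radiomics literature. Gray levels are obtained by equal-width
quantization of the ROI's own min–max range into ``L`` levels
(default 32). Undefined values (zero-variance correlations, coarseness
of a constant image) follow a documented NaN policy: they are replaced
by 0, except coarseness which is capped at ``COARSENESS_CAP``.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .images import as_pixel_array

__all__ = [
    "GROUP_SIZES",
    "quantize",
    "fos_features",
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "extract_all",
    "RadiomicFeatureExtractor",
]

logger = logging.getLogger(__name__)

GROUP_SIZES = {"FOS": 17, "GLCM": 22, "GLDM": 14, "GLRLM": 16, "GLSZM": 16, "NGTDM": 5}

COARSENESS_CAP = 1e6

# distance-1 offsets of the four unique 2D directions: 0, 45, 90, 135 degrees
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def _finalize(features: dict[str, float], group: str) -> dict[str, float]:
    """Apply the NaN policy: non-finite values become 0 with a warning."""
    out = {}
    for name, value in features.items():
        v = float(value)
        if not math.isfinite(v):
            logger.warning("%s feature %s undefined; set to 0", group, name)
            v = 0.0
        out[name] = v + 0.0  # normalize -0.0
    return out


def quantize(image, n_levels: int = 32) -> np.ndarray:
    """Equal-width quantization into integer gray levels 1..n_levels.

    Bins span the ROI's own [min, max]; the maximum maps to level
    ``n_levels``; a constant image maps entirely to level 1.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    x = as_pixel_array(image)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.ones(x.shape, dtype=np.int64)
    levels = np.floor((x - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(levels, 1, n_levels)


# ---------------------------------------------------------------------------
# first-order statistics


def fos_features(image, n_levels: int = 32) -> dict[str, float]:
    """The 17 first-order statistics of the intensity distribution.

    ``Entropy`` is computed on the equal-width ``n_levels`` histogram;
    skewness and kurtosis use the population moment estimators (kurtosis
    is reported non-excess, i.e. a Gaussian scores ~3); a constant image
    scores 0 on both per the NaN policy.
    """
    x = as_pixel_array(image).ravel()
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    counts = np.bincount(quantize(x.reshape(1, -1), n_levels).ravel())[1:]
    p = counts[counts > 0] / n
    sd = math.sqrt(var)
    if var > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / var**2)
    else:
        skew = kurt = float("nan")
    feats = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float((x**2).sum()),  # unit pixel area
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
    }
    return _finalize(feats, "FOS")


# ---------------------------------------------------------------------------
# gray-level co-occurrence matrix


def _glcm_matrix(levels: np.ndarray, n_levels: int, offset: tuple[int, int],
                 distance: int) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix for one offset."""
    dr, dc = offset[0] * distance, offset[1] * distance
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    mat = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(mat, (a.ravel() - 1, b.ravel() - 1), 1.0)
    mat = mat + mat.T
    total = mat.sum()
    return mat / total if total > 0 else mat


def _glcm_direction_features(p: np.ndarray, n_levels: int) -> dict[str, float]:
    i = np.arange(1, n_levels + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = math.sqrt(float(((i - mu_x) ** 2 * px).sum()))
    sig_y = math.sqrt(float(((i - mu_y) ** 2 * py).sum()))
    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(0, n_levels, dtype=float)
    p_diff = np.array(
        [p[np.abs(ii - jj) == k].sum() for k in k_diff]
    )
    k_sum = np.arange(2, 2 * n_levels + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    def _ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum()) if q.size else 0.0

    hxy = _ent(p.ravel())
    hx = _ent(px)
    hy = _ent(py)
    outer = np.outer(px, py)
    mask = (p > 0) & (outer > 0)
    hxy1 = float(-(p[mask] * np.log2(outer[mask])).sum())
    hxy2 = _ent(outer.ravel())
    da = float((k_diff * p_diff).sum())
    corr_num = float((ii * jj * p).sum()) - mu_x * mu_y
    off_diag = ii != jj
    feats = {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float((((ii + jj) - mu_x - mu_y) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - mu_x - mu_y) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - mu_x - mu_y) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": corr_num / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else float("nan"),
        "DifferenceAverage": da,
        "DifferenceEntropy": _ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / n_levels) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / n_levels)).sum()),
        "InverseVariance": float((p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumEntropy": _ent(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
    }
    return feats


def glcm_features(levels: np.ndarray, n_levels: int | None = None,
                  distance: int = 1) -> dict[str, float]:
    """The 22 co-occurrence features, averaged over the four directions."""
    levels = np.asarray(levels)
    if n_levels is None:
        n_levels = int(levels.max())
    per_dir = [
        _glcm_direction_features(
            _glcm_matrix(levels, n_levels, off, distance), n_levels
        )
        for off in _DIRECTIONS
    ]
    feats = {}
    for name in per_dir[0]:
        vals = [d[name] for d in per_dir if math.isfinite(d[name])]
        feats[name] = float(np.mean(vals)) if vals else float("nan")
    return _finalize(feats, "GLCM")


# ---------------------------------------------------------------------------
# gray-level dependence matrix


def _neighbor_stack(levels: np.ndarray) -> np.ndarray:
    """Stack of the 8 shifted neighbor maps (NaN outside the image)."""
    h, w = levels.shape
    padded = np.full((h + 2, w + 2), np.nan)
    padded[1:-1, 1:-1] = levels
    shifts = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifts.append(padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w])
    return np.stack(shifts)


def _dependence_matrix(levels: np.ndarray, n_levels: int, alpha: float) -> np.ndarray:
    neigh = _neighbor_stack(levels.astype(float))
    dep = np.nansum(np.abs(neigh - levels) <= alpha, axis=0).astype(np.int64)
    mat = np.zeros((n_levels, 9), dtype=float)
    np.add.at(mat, (levels.ravel() - 1, dep.ravel()), 1.0)
    return mat


def _size_distribution_features(
    mat: np.ndarray, n_pixels: int, names: dict[str, str]
) -> dict[str, float]:
    """Shared GLRLM/GLSZM/GLDM-style features of a (level x size) matrix.

    ``mat[i-1, j-1]`` counts occurrences of gray level i with size j
    (run length, zone size, or dependence). ``names`` maps the canonical
    slots to group-specific feature names.
    """
    nz = mat.sum()
    if nz == 0:
        return {v: 0.0 for v in names.values()}
    p = mat / nz
    n_levels, n_sizes = mat.shape
    i = np.arange(1, n_levels + 1, dtype=float)[:, None]
    j = np.arange(1, n_sizes + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((i.ravel() * pg).sum())
    mu_j = float((j.ravel() * ps).sum())
    pnz = p[p > 0]
    feats = {
        names["small"]: float((p / j**2).sum()),
        names["large"]: float((p * j**2).sum()),
        names["gln"]: float((mat.sum(axis=1) ** 2).sum() / nz),
        names["glnn"]: float((pg**2).sum()),
        names["sn"]: float((mat.sum(axis=0) ** 2).sum() / nz),
        names["snn"]: float((ps**2).sum()),
        names["percentage"]: float(nz / n_pixels),
        names["glv"]: float((p * (i - mu_i) ** 2).sum()),
        names["sv"]: float((p * (j - mu_j) ** 2).sum()),
        names["entropy"]: float(-(pnz * np.log2(pnz)).sum()),
        names["lgle"]: float((p / i**2).sum()),
        names["hgle"]: float((p * i**2).sum()),
        names["small_lgl"]: float((p / (i**2 * j**2)).sum()),
        names["small_hgl"]: float((p * i**2 / j**2).sum()),
        names["large_lgl"]: float((p * j**2 / i**2).sum()),
        names["large_hgl"]: float((p * i**2 * j**2).sum()),
    }
    return feats


def gldm_features(levels: np.ndarray, n_levels: int | None = None,
                  alpha: float = 0.0) -> dict[str, float]:
    """The 14 gray-level dependence features.

    The dependence of a pixel is the number of its 8-connected in-bounds
    neighbors whose gray level differs by at most ``alpha``; dependence
    size j = dependence + 1.
    """
    levels = np.asarray(levels)
    if n_levels is None:
        n_levels = int(levels.max())
    mat = _dependence_matrix(levels, n_levels, alpha)
    nz = mat.sum()
    p = mat / nz
    i = np.arange(1, n_levels + 1, dtype=float)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]  # dependence + 1
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((i.ravel() * pg).sum())
    mu_j = float((j.ravel() * ps).sum())
    pnz = p[p > 0]
    feats = {
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((ps**2).sum()),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }
    return _finalize(feats, "GLDM")


# ---------------------------------------------------------------------------
# gray-level run-length matrix


def _runs_along(line: np.ndarray) -> list[tuple[int, int]]:
    """(level, run length) pairs of one line of gray levels."""
    runs = []
    start = 0
    for k in range(1, len(line) + 1):
        if k == len(line) or line[k] != line[start]:
            runs.append((int(line[start]), k - start))
            start = k
    return runs


def _direction_lines(levels: np.ndarray, direction: tuple[int, int]):
    h, w = levels.shape
    if direction == (0, 1):
        yield from levels
    elif direction == (-1, 0):
        yield from levels.T
    elif direction == (-1, 1):  # anti-diagonals
        flipped = np.fliplr(levels)
        for k in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=k)
    elif direction == (-1, -1):  # main diagonals
        for k in range(-(h - 1), w):
            yield np.diagonal(levels, offset=k)
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {direction}")


def _rlm_matrix(levels: np.ndarray, n_levels: int,
                direction: tuple[int, int]) -> np.ndarray:
    max_run = max(levels.shape)
    mat = np.zeros((n_levels, max_run), dtype=float)
    for line in _direction_lines(levels, direction):
        if len(line) == 0:
            continue
        for level, length in _runs_along(np.asarray(line)):
            mat[level - 1, length - 1] += 1.0
    return mat


_RLM_NAMES = {
    "small": "ShortRunEmphasis",
    "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity",
    "snn": "RunLengthNonUniformityNormalized",
    "percentage": "RunPercentage",
    "glv": "GrayLevelVariance",
    "sv": "RunVariance",
    "entropy": "RunEntropy",
    "lgle": "LowGrayLevelRunEmphasis",
    "hgle": "HighGrayLevelRunEmphasis",
    "small_lgl": "ShortRunLowGrayLevelEmphasis",
    "small_hgl": "ShortRunHighGrayLevelEmphasis",
    "large_lgl": "LongRunLowGrayLevelEmphasis",
    "large_hgl": "LongRunHighGrayLevelEmphasis",
}

_SZM_NAMES = {
    "small": "SmallAreaEmphasis",
    "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity",
    "snn": "SizeZoneNonUniformityNormalized",
    "percentage": "ZonePercentage",
    "glv": "GrayLevelVariance",
    "sv": "ZoneVariance",
    "entropy": "ZoneEntropy",
    "lgle": "LowGrayLevelZoneEmphasis",
    "hgle": "HighGrayLevelZoneEmphasis",
    "small_lgl": "SmallAreaLowGrayLevelEmphasis",
    "small_hgl": "SmallAreaHighGrayLevelEmphasis",
    "large_lgl": "LargeAreaLowGrayLevelEmphasis",
    "large_hgl": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """The 16 run-length features, averaged over the four directions."""
    levels = np.asarray(levels)
    if n_levels is None:
        n_levels = int(levels.max())
    n_pixels = levels.size
    per_dir = []
    for direction in _DIRECTIONS:
        mat = _rlm_matrix(levels, n_levels, direction)
        per_dir.append(_size_distribution_features(mat, n_pixels, _RLM_NAMES))
    names = per_dir[0].keys()
    feats = {name: float(np.mean([d[name] for d in per_dir])) for name in names}
    return _finalize(feats, "GLRLM")


# ---------------------------------------------------------------------------
# gray-level size-zone matrix


def _szm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    max_zone = levels.size
    sizes: list[tuple[int, int]] = []
    for level in np.unique(levels):
        labeled, n_zones = ndimage.label(levels == level, structure=_EIGHT_CONNECTED)
        if n_zones:
            counts = np.bincount(labeled.ravel())[1:]
            sizes.extend((int(level), int(c)) for c in counts)
    mat = np.zeros((n_levels, max_zone), dtype=float)
    for level, size in sizes:
        mat[level - 1, size - 1] += 1.0
    return mat


def glszm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """The 16 size-zone features (8-connected zones, direction-free)."""
    levels = np.asarray(levels)
    if n_levels is None:
        n_levels = int(levels.max())
    mat = _szm_matrix(levels, n_levels)
    feats = _size_distribution_features(mat, levels.size, _SZM_NAMES)
    return _finalize(feats, "GLSZM")


# ---------------------------------------------------------------------------
# neighborhood gray-tone difference matrix


def ngtdm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """The 5 neighborhood gray-tone difference features.

    For each pixel the absolute difference between its gray level and
    the mean of its in-bounds 8-neighbors is accumulated per level;
    coarseness of a constant image is capped at ``COARSENESS_CAP``.
    """
    levels = np.asarray(levels)
    if n_levels is None:
        n_levels = int(levels.max())
    n_pixels = levels.size
    neigh = _neighbor_stack(levels.astype(float))
    with np.errstate(invalid="ignore"):
        nbr_mean = np.nanmean(neigh, axis=0)
    diff = np.abs(levels - nbr_mean)
    s = np.zeros(n_levels)
    n_i = np.zeros(n_levels)
    np.add.at(s, levels.ravel() - 1, diff.ravel())
    np.add.at(n_i, levels.ravel() - 1, 1.0)
    p_i = n_i / n_pixels
    present = n_i > 0
    ngp = int(present.sum())
    i_vals = np.arange(1, n_levels + 1, dtype=float)
    ip = i_vals[present]
    pp = p_i[present]
    sp = s[present]

    sum_ps = float((p_i * s).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else COARSENESS_CAP

    if ngp > 1:
        dij2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = (
            float((pp[:, None] * pp[None, :] * dij2).sum())
            / (ngp * (ngp - 1))
            * (s.sum() / n_pixels)
        )
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        pair_sum = pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]
        pair_p = pp[:, None] + pp[None, :]
        complexity = float(
            (np.abs(ip[:, None] - ip[None, :]) * pair_sum / pair_p).sum()
        ) / n_pixels
        s_total = float(s.sum())
        strength = (
            float((pair_p * dij2).sum()) / s_total if s_total > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    feats = {
        "Coarseness": min(coarseness, COARSENESS_CAP),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
    return _finalize(feats, "NGTDM")


# ---------------------------------------------------------------------------
# assembly


def extract_all(image, n_levels: int = 32, glcm_distance: int = 1,
                gldm_alpha: float = 0.0) -> dict[str, float]:
    """All 90 statistical features (17 FOS + 73 SOS), prefixed by group."""
    levels = quantize(image, n_levels)
    out: dict[str, float] = {}
    groups = {
        "FOS": fos_features(image, n_levels),
        "GLCM": glcm_features(levels, n_levels, glcm_distance),
        "GLDM": gldm_features(levels, n_levels, gldm_alpha),
        "GLRLM": glrlm_features(levels, n_levels),
        "GLSZM": glszm_features(levels, n_levels),
        "NGTDM": ngtdm_features(levels, n_levels),
    }
    for group, feats in groups.items():
        if len(feats) != GROUP_SIZES[group]:  # contract guard
            raise RuntimeError(
                f"{group} produced {len(feats)} features, expected {GROUP_SIZES[group]}"
            )
        for name, value in feats.items():
            out[f"{group}_{name}"] = value
    return out


class RadiomicFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer computing the 90-column statistical feature block.

    ``transform`` maps a sequence of images (2D arrays or RoiImage) to
    an ``(n_images, 90)`` array; column names are available through
    :meth:`get_feature_names_out`. Stateless.
    """

    def __init__(self, n_levels: int = 32, glcm_distance: int = 1,
                 gldm_alpha: float = 0.0) -> None:
        self.n_levels = n_levels
        self.glcm_distance = glcm_distance
        self.gldm_alpha = gldm_alpha

    def fit(self, X: Iterable = (), y=None) -> "RadiomicFeatureExtractor":
        probe = extract_all(
            np.arange(16.0).reshape(4, 4),
            self.n_levels, self.glcm_distance, self.gldm_alpha,
        )
        self.feature_names_out_ = np.asarray(list(probe), dtype=object)
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        rows = []
        for image in X:
            feats = extract_all(
                image, self.n_levels, self.glcm_distance, self.gldm_alpha
            )
            rows.append([feats[name] for name in self.feature_names_out_])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        return self.feature_names_out_
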