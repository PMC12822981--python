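"""Independent brute-force twins of the optimized implementations.

Everything here is written as plain double loops over explicit window
or pixel enumerations, deliberately sharing no code with the package,
so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.special import ndtr


# ---------------------------------------------------------------------------
# entropy oracles


def _window_list(x, m):
    h, w = x.shape
    return [
        x[i : i + m, j : j + m].ravel()
        for i in range(h - m + 1)
        for j in range(w - m + 1)
    ]


def _common_window_lists(x, m):
    """m and m+1 windows at positions where the (m+1) window fits."""
    h, w = x.shape
    small, big = [], []
    for i in range(h - m):
        for j in range(w - m):
            small.append(x[i : i + m, j : j + m].ravel())
            big.append(x[i : i + m + 1, j : j + m + 1].ravel())
    return small, big


def _cheb(a, b):
    return float(np.max(np.abs(a - b)))


def sampen2d_brute(x, m, r):
    small, big = _common_window_lists(np.asarray(x, float), m)
    n = len(small)
    b_count = a_count = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if _cheb(small[i], small[j]) <= r:
                b_count += 1
            if _cheb(big[i], big[j]) <= r:
                a_count += 1
    if a_count == 0 or b_count == 0:
        return float("nan")
    return -math.log(a_count / b_count)


def fuzzen2d_brute(x, m, r, n_exp):
    small, big = _common_window_lists(np.asarray(x, float), m)
    small = [w - w.mean() for w in small]
    big = [w - w.mean() for w in big]
    n = len(small)
    phi_m = phi_m1 = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            phi_m += math.exp(-(_cheb(small[i], small[j]) ** n_exp) / r)
            phi_m1 += math.exp(-(_cheb(big[i], big[j]) ** n_exp) / r)
            pairs += 1
    return -math.log((phi_m1 / pairs) / (phi_m / pairs))


def permen2d_brute(x, m):
    windows = _window_list(np.asarray(x, float), m)
    patterns = Counter()
    for w in windows:
        # stable sort: ties broken by earlier index
        order = tuple(sorted(range(len(w)), key=lambda k: (w[k], k)))
        patterns[order] += 1
    total = sum(patterns.values())
    h = -sum((c / total) * math.log(c / total) for c in patterns.values())
    return h / math.log(math.factorial(m * m))


def dispen2d_brute(x, m, c):
    x = np.asarray(x, float)
    mu, sd = x.mean(), x.std()
    if sd == 0:
        classes = np.full(x.shape, round((c + 1) / 2), dtype=int)
    else:
        y = ndtr((x - mu) / sd)
        classes = np.clip(np.round(c * y + 0.5).astype(int), 1, c)
    patterns = Counter(tuple(w.astype(int)) for w in _window_list(classes.astype(float), m))
    total = sum(patterns.values())
    h = -sum((k / total) * math.log(k / total) for k in patterns.values())
    return h / math.log(c ** (m * m))


def disten2d_brute(x, m, bins):
    windows = _window_list(np.asarray(x, float), m)
    dists = [
        _cheb(windows[i], windows[j])
        for i in range(len(windows))
        for j in range(i + 1, len(windows))
    ]
    dmax = max(dists)
    if dmax == 0:
        return 0.0
    counts = [0] * bins
    for d in dists:
        k = min(int(d / dmax * bins), bins - 1)
        counts[k] += 1
    total = len(dists)
    h = -sum((c / total) * math.log2(c / total) for c in counts if c > 0)
    return h / math.log2(bins)


# ---------------------------------------------------------------------------
# filter oracle


def median_filter_brute(x, radius):
    x = np.asarray(x, float)
    h, w = x.shape
    out = np.empty_like(x)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    ii = min(max(i + di, 0), h - 1)  # replicate padding
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(x[ii, jj])
            out[i, j] = sorted(vals)[len(vals) // 2]
    return out


# ---------------------------------------------------------------------------
# gray-level matrix oracles


def glcm_matrix_brute(levels, n_levels, offset):
    levels = np.asarray(levels)
    h, w = levels.shape
    mat = np.zeros((n_levels, n_levels))
    dr, dc = offset
    for i in range(h):
        for j in range(w):
            ii, jj = i + dr, j + dc
            if 0 <= ii < h and 0 <= jj < w:
                mat[levels[i, j] - 1, levels[ii, jj] - 1] += 1
    mat = mat + mat.T
    return mat / mat.sum() if mat.sum() else mat


def rlm_matrix_brute(levels, n_levels, direction):
    """Run-length matrix by explicit line walking."""
    levels = np.asarray(levels)
    h, w = levels.shape
    max_run = max(h, w)
    mat = np.zeros((n_levels, max_run))
    dr, dc = {"h": (0, 1), "v": (1, 0), "d": (1, 1), "a": (1, -1)}[direction]
    starts = []
    for i in range(h):
        for j in range(w):
            pi, pj = i - dr, j - dc
            if not (0 <= pi < h and 0 <= pj < w):
                starts.append((i, j))
    for i0, j0 in starts:
        i, j = i0, j0
        run_level, run_len = levels[i, j], 0
        while 0 <= i < h and 0 <= j < w:
            if levels[i, j] == run_level:
                run_len += 1
            else:
                mat[run_level - 1, run_len - 1] += 1
                run_level, run_len = levels[i, j], 1
            i, j = i + dr, j + dc
        mat[run_level - 1, run_len - 1] += 1
    return mat


def szm_sizes_brute(levels):
    """(level, zone size) pairs by explicit 8-connected flood fill."""
    levels = np.asarray(levels)
    h, w = levels.shape
    seen = np.zeros((h, w), bool)
    zones = []
    for i in range(h):
        for j in range(w):
            if seen[i, j]:
                continue
            level = levels[i, j]
            stack, size = [(i, j)], 0
            seen[i, j] = True
            while stack:
                a, b = stack.pop()
                size += 1
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        aa, bb = a + da, b + db
                        if (
                            0 <= aa < h and 0 <= bb < w
                            and not seen[aa, bb]
                            and levels[aa, bb] == level
                        ):
                            seen[aa, bb] = True
                            stack.append((aa, bb))
            zones.append((int(level), size))
    return sorted(zones)


def gldm_matrix_brute(levels, n_levels, alpha):
    levels = np.asarray(levels)
    h, w = levels.shape
    mat = np.zeros((n_levels, 9))
    for i in range(h):
        for j in range(w):
            dep = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        if abs(int(levels[ii, jj]) - int(levels[i, j])) <= alpha:
                            dep += 1
            mat[levels[i, j] - 1, dep] += 1
    return mat


def ngtdm_vectors_brute(levels, n_levels):
    """(s_i, n_i) accumulators by direct neighborhood summation."""
    levels = np.asarray(levels)
    h, w = levels.shape
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w:
                        vals.append(levels[ii, jj])
            diff = abs(levels[i, j] - sum(vals) / len(vals))
            s[levels[i, j] - 1] += diff
            n[levels[i, j] - 1] += 1
    return s, n
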