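"""Independent brute-force oracles used to check the fast implementations.

Everything here is written as literal loops over definitions, deliberately
sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_bruteforce(grid: np.ndarray, levels: int, dx: int, dy: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by double-loop pair counting."""
    h, w = grid.shape
    mat = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = grid[r, c], grid[r2, c2]
                mat[a, b] += 1
                mat[b, a] += 1
    return mat / mat.sum()


def haralick_bruteforce(p: np.ndarray, log=math.log) -> dict:
    """Eleven Haralick descriptors by literal summation over the matrix."""
    n = p.shape[0]
    out = {}
    out["AngScMom"] = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    out["Contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    mu_x = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_y = sum(j * p[i, j] for i in range(n) for j in range(n))
    var_x = sum((i - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_y = sum((j - mu_y) ** 2 * p[i, j] for i in range(n) for j in range(n))
    if var_x > 0 and var_y > 0:
        out["Correlat"] = (
            sum(i * j * p[i, j] for i in range(n) for j in range(n)) - mu_x * mu_y
        ) / math.sqrt(var_x * var_y)
    else:
        out["Correlat"] = float("nan")
    out["SumOfSqs"] = var_x
    out["InvDfMom"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    out["SumAverg"] = sum(k * p_sum[k] for k in range(2 * n - 1))
    out["SumVarnc"] = sum((k - out["SumAverg"]) ** 2 * p_sum[k] for k in range(2 * n - 1))
    out["SumEntrp"] = -sum(v * log(v) for v in p_sum if v > 0)
    out["Entropy"] = -sum(p[i, j] * log(p[i, j]) for i in range(n) for j in range(n)
                          if p[i, j] > 0)
    mu_d = sum(k * p_diff[k] for k in range(n))
    out["DifVarnc"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(n))
    out["DifEntrp"] = -sum(v * log(v) for v in p_diff if v > 0)
    return out


def _scan_lines(grid: np.ndarray, direction: str):
    """Enumerate lattice lines by explicitly walking the step vector."""
    h, w = grid.shape
    step = {"Horzl": (1, 0), "Vertl": (0, 1), "45dgr": (1, -1), "135dr": (1, 1)}[direction]
    dx, dy = step
    starts = []
    for y in range(h):
        for x in range(w):
            px, py = x - dx, y - dy  # predecessor on the same line
            if not (0 <= px < w and 0 <= py < h):
                starts.append((x, y))
    for x0, y0 in starts:
        line = []
        x, y = x0, y0
        while 0 <= x < w and 0 <= y < h:
            line.append(grid[y, x])
            x, y = x + dx, y + dy
        yield line


def rlm_bruteforce(grid: np.ndarray, levels: int, direction: str) -> dict:
    """Galloway run-length descriptors from an explicit line-scanning counter."""
    runs = []  # (level, length)
    npix = 0
    for line in _scan_lines(grid, direction):
        npix += len(line)
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            runs.append((line[i], j - i))
            i = j
    assert npix == grid.size
    c = len(runs)
    out = {}
    out["ShrtREmp"] = sum(1.0 / k**2 for _, k in runs) / c
    out["LngREmp"] = sum(float(k**2) for _, k in runs) / c
    level_totals = {}
    length_totals = {}
    for lev, k in runs:
        level_totals[lev] = level_totals.get(lev, 0) + 1
        length_totals[k] = length_totals.get(k, 0) + 1
    out["GLevNonU"] = sum(v**2 for v in level_totals.values()) / c
    out["RLNonUni"] = sum(v**2 for v in length_totals.values()) / c
    out["Fraction"] = c / sum(k for _, k in runs)
    return out


def moments_bruteforce(x: np.ndarray) -> dict:
    """Mean/population-variance/skewness/excess-kurtosis by direct summation."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    out = {"Mean": mean, "Variance": var}
    if var > 0:
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        out["Skewness"] = m3 / var**1.5
        out["Kurtosis"] = m4 / var**2 - 3.0
    return out


def gradient_bruteforce(patch: np.ndarray) -> np.ndarray:
    """Interior central-difference gradient magnitude, pixel by pixel."""
    px = np.asarray(patch, dtype=float)
    h, w = px.shape
    g = np.zeros((h - 2, w - 2))
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            gx = px[y, x + 1] - px[y, x - 1]
            gy = px[y + 1, x] - px[y - 1, x]
            g[y - 1, x - 1] = math.sqrt(gx**2 + gy**2)
    return g


def auc_pair_counting(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as P(pos > neg) + 0.5 P(tie) by explicit pair enumeration."""
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def kruskal_h_direct(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from the rank-sum formula."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty_like(pooled)
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank, 1-based
        i = j
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g)
        r = ranks[start : start + g.size].sum()
        h += r**2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    return h / correction


def vif_inverse_correlation(X: np.ndarray) -> np.ndarray:
    """VIF as the diagonal of the inverse correlation matrix."""
    corr = np.corrcoef(np.asarray(X, dtype=float), rowvar=False)
    return np.diag(np.linalg.inv(corr))
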