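"""Naive, loop-based reference implementations used as independent oracles.

These deliberately avoid the vectorised code paths of the package:
plain double loops and per-element scans, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def naive_recurrence(dist: np.ndarray, lam: float) -> np.ndarray:
    n = dist.shape[0]
    out = np.empty((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            out[i, j] = 0 if dist[i, j] <= lam else 1
    return out


def naive_diagonal_runs(entries: np.ndarray) -> dict[int, int]:
    """Zero-run lengths along all diagonals parallel to (excluding) the LOI."""
    n = entries.shape[0]
    counts: dict[int, int] = {}
    for off in range(-(n - 1), n):
        if off == 0:
            continue
        run = 0
        cells = []
        for i in range(n):
            j = i + off
            if 0 <= j < n:
                cells.append(entries[i, j])
        for v in cells + [1]:  # sentinel terminates a trailing run
            if v == 0:
                run += 1
            else:
                if run > 0:
                    counts[run] = counts.get(run, 0) + 1
                run = 0
    return counts


def naive_entropy(counts: dict[int, int]) -> float:
    total = sum(counts.values())
    s = 0.0
    for c in counts.values():
        p = c / total
        s -= p * math.log(p)
    return s + 0.0


def naive_sma(w, k: int) -> list[float]:
    n = len(w)
    out = []
    for i in range(n):
        lo = max(0, i - (k - 1) // 2)
        hi = min(n - 1, i + k // 2)
        win = [w[j] for j in range(lo, hi + 1)]
        out.append(sum(win) / len(win))
    return out


def naive_z(w) -> list[float]:
    n = len(w)
    mean = sum(w) / n
    var = sum((v - mean) ** 2 for v in w) / n
    sd = math.sqrt(var)
    return [(v - mean) / sd for v in w]


def naive_detect(entries: np.ndarray, threshold: float, polarity: str,
                 k_grid) -> tuple[int, list[int], list[float]]:
    """Steps a-f of cross detection, rewritten with plain loops.

    Returns (k, 1-based centers, scores on the dark-weight scale);
    (0, [], []) when every candidate smoothing degenerates.
    """
    n = entries.shape[0]
    w = []
    for i in range(n):
        ones = sum(int(entries[j, i]) for j in range(n))
        w.append(float(ones if polarity == "dark" else n - ones))
    best_k, best_obj = None, -float("inf")
    for k in sorted(set(int(k) for k in k_grid)):
        sm = naive_sma(w, k)
        if max(sm) == min(sm):
            continue
        obj = max(naive_z(sm))
        if obj > best_obj + 1e-12:
            best_obj, best_k = obj, k
    if best_k is None:
        return 0, [], []
    z = naive_z(naive_sma(w, best_k))
    # strict local maxima, plateau midpoints, boundaries vs inner neighbour
    cand = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and z[j + 1] == z[i]:
            j += 1
        left = i == 0 or z[i - 1] < z[i]
        right = j == n - 1 or z[j + 1] < z[i]
        if left and right and not (i == 0 and j == n - 1):
            cand.append((i + j) // 2)
        i = j + 1
    cand = [c for c in cand if z[c] > threshold]
    accepted: list[int] = []
    for c in sorted(cand, key=lambda c: (-z[c], c)):
        if all(abs(c - a) >= best_k for a in accepted):
            accepted.append(c)
    accepted.sort()
    sign = 1.0 if polarity == "dark" else -1.0
    return best_k, [c + 1 for c in accepted], [sign * z[c] for c in accepted]


def naive_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation with the biased (1/L) covariance estimator."""
    x = np.asarray(x, float)
    L = x.size
    xc = x - x.mean()
    denom = float(np.sum(xc * xc))
    r = np.empty(max_lag + 1)
    for h in range(max_lag + 1):
        r[h] = float(np.sum(xc[: L - h] * xc[h:])) / denom
    return r


def naive_cao_e1(x: np.ndarray, tau: int, max_m: int) -> list[float]:
    """E1(m) for m = 1..max_m via an O(n^2) double loop, maximum norm."""

    def vec(i, m):
        return [x[i + t * tau] for t in range(m)]

    def cheb(a, b):
        return max(abs(u - v) for u, v in zip(a, b))

    e = []
    for m in range(1, max_m + 2):
        n = len(x) - m * tau
        ratios = []
        for i in range(n):
            vi = vec(i, m)
            best_j, best_d = None, float("inf")
            for j in range(n):
                if j == i:
                    continue
                d = cheb(vi, vec(j, m))
                if 0 < d < best_d:
                    best_d, best_j = d, j
            if best_j is None:
                continue
            d_up = cheb(vec(i, m + 1), vec(best_j, m + 1))
            ratios.append(d_up / best_d)
        e.append(sum(ratios) / len(ratios))
    return [e[m] / e[m - 1] for m in range(1, max_m + 1)]
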