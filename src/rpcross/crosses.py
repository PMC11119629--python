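"""Automatic detection of dark/white crosses on a recurrence plot.

A dark cross is a full-width band of non-recurrent (black) pixels
crossing the main diagonal: the sub-series inside the band are far
from everything else, marking a time window whose dynamics differ
from the rest of the series.  Detection works on the column-wise
weight of the plot,

    w_i = sum_i' m[i, i'],

smoothed by a simple moving average of width k, standardised to
z-scores, with k chosen to maximise the highest standardised value
(the cross width estimate); cross centres are then the local maxima
exceeding a standard-score threshold.  White crosses (bands of
recurrent pixels) are the mirror case: the same procedure on the
count of zeros per column, i.e. the complemented weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateSeriesError
from .recurrence import RecurrenceMatrix

__all__ = [
    "WeightVector",
    "CrossDetectionResult",
    "column_weights",
    "smooth_sma",
    "standardize",
    "select_k",
    "detect_crosses",
]


@dataclass
class WeightVector:
    """Column weights of a recurrence plot, optionally smoothed/z-scored."""

    weights: np.ndarray
    polarity: str = "dark"
    smoothed: Optional[np.ndarray] = None
    zscores: Optional[np.ndarray] = None
    k: Optional[int] = None


@dataclass
class CrossDetectionResult:
    """Detected crosses: width k, 1-based centre indices, z-scores.

    ``center_scores`` are on the dark-weight scale: dark-cross centres
    score above ``threshold_sigma``, white-cross centres below
    ``-threshold_sigma``.  Centres are at least k apart.
    ``no_structure`` is set when the weight vector was constant and no
    detection was possible.
    """

    k: int
    centers: list[int]
    center_scores: list[float]
    threshold_sigma: float
    polarity: str
    no_structure: bool = False
    zscores: Optional[np.ndarray] = None

    @property
    def n_crosses(self) -> int:
        return len(self.centers)

    def center_times(self, dt: float = 1.0) -> list[float]:
        """Centre positions in time units (sub-series i starts at (i-1)*dt)."""
        return [(c - 1) * dt for c in self.centers]


def column_weights(M: RecurrenceMatrix, polarity: str = "dark") -> WeightVector:
    """Column sums of ones (dark) or zeros (white) of the matrix."""
    if polarity not in ("dark", "white"):
        raise ConfigurationError(f"polarity must be 'dark' or 'white', got {polarity!r}")
    ones = M.entries.sum(axis=0).astype(float)
    w = ones if polarity == "dark" else M.side - ones
    return WeightVector(weights=w, polarity=polarity)


def smooth_sma(w: np.ndarray, k: int) -> np.ndarray:
    """Centred simple moving average of width k, truncated at the edges.

    The output keeps the input length so index/time alignment
    survives.  Even k spans k points biased one step to the right;
    near the edges the window is truncated to the available points.
    """
    w = np.asarray(w, dtype=float)
    n = w.size
    if not (1 <= k <= n):
        raise ConfigurationError(f"SMA width k={k} out of range 1..{n}")
    if k == 1:
        return w.copy()
    csum = np.concatenate(([0.0], np.cumsum(w)))
    i = np.arange(n)
    lo = np.maximum(0, i - (k - 1) // 2)
    hi = np.minimum(n - 1, i + k // 2)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def standardize(w: np.ndarray) -> np.ndarray:
    """Z-scores with the population (divisor n) standard deviation."""
    w = np.asarray(w, dtype=float)
    sigma = float(np.std(w))
    if sigma == 0:
        raise DegenerateSeriesError("constant weight vector; z-scores undefined")
    return (w - np.mean(w)) / sigma


def select_k(w: np.ndarray, k_grid: Sequence[int]) -> Optional[int]:
    """Smoothing width maximising the peak standardised smoothed weight.

    Ties break to the smallest k.  Candidates whose smoothed vector is
    constant are skipped; if every candidate degenerates there is no
    structure to measure and None is returned.
    """
    w = np.asarray(w, dtype=float)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ConfigurationError("empty k grid")
    best_k, best_obj = None, -np.inf
    for k in k_grid:
        try:
            z = standardize(smooth_sma(w, k))
        except DegenerateSeriesError:
            continue
        obj = float(np.max(z))
        if obj > best_obj + 1e-12:
            best_obj, best_k = obj, k
    return best_k


def _local_maxima(z: np.ndarray) -> list[int]:
    """Strict local maxima (0-based); plateaus contribute their midpoint.

    Boundary points count when they exceed their single inner
    neighbour, so a band at the very start or end of the series is
    still detectable.
    """
    n = z.size
    if n == 1:
        return [0]
    maxima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and z[j + 1] == z[i]:
            j += 1
        left_lower = i == 0 or z[i - 1] < z[i]
        right_lower = j == n - 1 or z[j + 1] < z[i]
        if left_lower and right_lower and not (i == 0 and j == n - 1):
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def detect_crosses(
    M: RecurrenceMatrix,
    threshold_sigma: float = 2.5,
    polarity: str = "dark",
    k_grid: Optional[Sequence[int]] = None,
) -> CrossDetectionResult:
    """Full cross detection: weights -> SMA(k) -> z-scores -> centres.

    ``k_grid`` defaults to 1..max(1, side // 4); capping the smoothing
    window at a quarter of the plot keeps one average from spanning
    unrelated regions.  Centres are local maxima of the standardised
    smoothed weight exceeding ``threshold_sigma``, thinned greedily in
    descending score order so surviving centres are at least k apart.
    Returned centre indices are 1-based sub-series numbers.
    """
    if threshold_sigma <= 0:
        raise ConfigurationError(f"threshold_sigma must be > 0, got {threshold_sigma}")
    side = M.side
    if k_grid is None:
        k_grid = range(1, max(1, side // 4) + 1)
    wv = column_weights(M, polarity=polarity)
    k = select_k(wv.weights, k_grid)
    if k is None:
        return CrossDetectionResult(
            k=0, centers=[], center_scores=[], threshold_sigma=threshold_sigma,
            polarity=polarity, no_structure=True,
        )
    z = standardize(smooth_sma(wv.weights, k))
    candidates = [i for i in _local_maxima(z) if z[i] > threshold_sigma]
    # greedy thinning, strongest first, minimum separation k
    accepted: list[int] = []
    for i in sorted(candidates, key=lambda i: (-z[i], i)):
        if all(abs(i - j) >= k for j in accepted):
            accepted.append(i)
    accepted.sort()
    sign = 1.0 if polarity == "dark" else -1.0
    return CrossDetectionResult(
        k=k,
        centers=[i + 1 for i in accepted],
        center_scores=[sign * float(z[i]) for i in accepted],
        threshold_sigma=threshold_sigma,
        polarity=polarity,
        zscores=sign * z,
    )
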