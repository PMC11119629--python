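"""Delay embedding of a scalar series and automatic parameter selection.

A scalar series x_1..x_L is compressed into the delay sub-series

    y_i(d, tau) = (x_i, x_{i+tau}, ..., x_{i+d*tau}),   i = 1..L - d*tau,

each of length d + 1: ``d`` is the embedding order (the sub-series
carries d + 1 coordinates; note the off-by-one relative to the usual
"embedding dimension m" of the delay-reconstruction literature, which
counts coordinates) and ``tau`` the delay in sample steps.

The delay is chosen as the first lag whose sample autocorrelation is
not significantly different from zero (white-noise band), and the
number of coordinates by the saturation of Cao's E1 statistic.  When
several series are analysed jointly, one value of each parameter is
fixed by majority voting so all recurrence plots are comparable.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm as _norm
from statsmodels.tsa.stattools import acf as _sm_acf

from .errors import (
    DegenerateSeriesError,
    EmbeddingLengthError,
    InsufficientDataError,
)
from .timeseries import TimeSeries

__all__ = [
    "EmbeddingParams",
    "EmbeddedSeries",
    "CaoResult",
    "embed",
    "delay_by_autocorrelation",
    "cao_dimension",
    "majority_vote",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay ``tau`` (sample steps) and embedding order ``dim``.

    A sub-series has ``dim + 1`` coordinates; a series of length L
    yields ``L - dim * tau`` sub-series and must satisfy
    ``L - dim * tau >= 2``.
    """

    tau: int
    dim: int

    def __post_init__(self) -> None:
        if int(self.tau) != self.tau or self.tau < 1:
            raise EmbeddingLengthError(f"tau must be a positive integer, got {self.tau}")
        if int(self.dim) != self.dim or self.dim < 1:
            raise EmbeddingLengthError(f"dim must be a positive integer, got {self.dim}")
        object.__setattr__(self, "tau", int(self.tau))
        object.__setattr__(self, "dim", int(self.dim))


@dataclass
class EmbeddedSeries:
    """The (L - dim*tau) x (dim + 1) array of delay sub-series.

    Row i (0-based storage; documentation counts sub-series from 1)
    holds (x_i, x_{i+tau}, ..., x_{i+dim*tau}).
    """

    rows: np.ndarray
    source_length: int
    params: EmbeddingParams
    label: str = ""

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]


def embed(series: TimeSeries, params: EmbeddingParams) -> EmbeddedSeries:
    """Compress a series into its delay sub-series.

    Raises
    ------
    EmbeddingLengthError
        If fewer than two sub-series would exist
        (L - dim*tau < 2).
    """
    x = series.values
    L = x.size
    n = L - params.dim * params.tau
    if n < 2:
        raise EmbeddingLengthError(
            f"series of length {L} too short for dim={params.dim}, "
            f"tau={params.tau} (would give {n} sub-series)"
        )
    offsets = np.arange(params.dim + 1) * params.tau
    rows = x[np.arange(n)[:, None] + offsets[None, :]]
    return EmbeddedSeries(rows=rows, source_length=L, params=params, label=series.label)


def delay_by_autocorrelation(series: TimeSeries, alpha: float = 0.05) -> int:
    """Delay tau = first lag with non-significant sample autocorrelation.

    Significance is judged against the large-sample white-noise band
    +/- z_{1-alpha/2} / sqrt(L).  Lags up to L // 2 are examined; if
    every one is significant, L // 2 is returned with a warning.

    Raises
    ------
    DegenerateSeriesError
        If the series has zero variance (ACF undefined).
    InsufficientDataError
        If the series is shorter than 10 samples.
    """
    x = series.values
    L = x.size
    if L < 10:
        raise InsufficientDataError(f"need >= 10 samples for the ACF, got {L}")
    if np.var(x) == 0:
        raise DegenerateSeriesError(
            f"series {series.label!r} has zero variance; ACF undefined"
        )
    max_lag = L // 2
    r = _sm_acf(x, nlags=max_lag, fft=True)
    band = _norm.ppf(1 - alpha / 2) / np.sqrt(L)
    inside = np.flatnonzero(np.abs(r[1:]) <= band)
    if inside.size == 0:
        warnings.warn(
            f"series {series.label!r}: no non-significant autocorrelation up "
            f"to lag {max_lag}; returning {max_lag}",
            stacklevel=2,
        )
        return max_lag
    return int(inside[0]) + 1


@dataclass
class CaoResult:
    """Outcome of the Cao minimum-embedding-dimension estimate.

    ``dim`` is the conventional embedding dimension: the minimal number
    of delay coordinates (an embedding order of ``dim - 1`` in the
    d+1-coordinate sub-series convention used by :func:`embed`).
    ``e1[m-1]`` and ``e2[m-1]`` hold E1(m) and E2(m).  ``saturated``
    is False when E1 never levelled off within tolerance up to
    ``max_dim`` — the signature of a noise-dominated series, for which
    E2(m) stays close to 1 at every m.
    """

    dim: int
    e1: np.ndarray
    e2: np.ndarray
    saturated: bool

    @property
    def noise_flag(self) -> bool:
        return not self.saturated

    def __int__(self) -> int:
        return self.dim


def _cao_stats(x: np.ndarray, tau: int, m: int) -> tuple[float, float]:
    """E(m) and E*(m) of Cao's method, maximum-norm neighbour distances.

    Uses the index range valid for (m+1)-coordinate vectors so the same
    pairs are comparable at both sizes; self-matches and exactly
    coincident points are excluded from the nearest-neighbour search.
    """
    L = x.size
    n = L - m * tau
    if n < 2:
        raise EmbeddingLengthError(
            f"length {L} too short for Cao statistics at m={m}, tau={tau}"
        )
    idx = np.arange(n)[:, None] + np.arange(m) * tau
    vm = x[idx]                      # (n, m) vectors
    extra = x[np.arange(n) + m * tau]  # the (m+1)-th coordinate
    dm = cdist(vm, vm, metric="chebyshev")
    np.fill_diagonal(dm, np.inf)
    dm[dm == 0] = np.inf
    nn = np.argmin(dm, axis=1)
    dnn = dm[np.arange(n), nn]
    ok = np.isfinite(dnn)
    if not np.any(ok):
        raise DegenerateSeriesError(
            "all pairwise distances are zero; Cao ratios undefined"
        )
    extra_gap = np.abs(extra - extra[nn])
    d_next = np.maximum(dnn, extra_gap)  # chebyshev distance at m+1 coords
    e = float(np.mean(d_next[ok] / dnn[ok]))
    e_star = float(np.mean(extra_gap[ok]))
    return e, e_star


def cao_dimension(
    series: TimeSeries,
    tau: int,
    max_dim: int = 10,
    e1_saturation: float = 0.05,
) -> CaoResult:
    """Minimum embedding dimension by the saturation of Cao's E1.

    E1(m) = E(m+1)/E(m), where E(m) averages over i the ratio of the
    maximum-norm distance between the i-th delay vector and its nearest
    neighbour at m+1 coordinates to the same distance at m coordinates.
    Returns the smallest m with both |E1(m) - 1| and |E1(m+1) - 1|
    within ``e1_saturation``; if no m saturates, ``max_dim`` is
    returned with ``saturated=False``.  E2(m) = E*(m+1)/E*(m) is
    reported alongside: E2 ~ 1 at every m marks a stochastic series.
    """
    x = series.values
    if np.var(x) == 0:
        raise DegenerateSeriesError(
            f"series {series.label!r} has zero variance"
        )
    # the search needs E(m) up to max_dim + 2; on short series (or large
    # tau) the cap shrinks to the largest feasible dimension
    feasible = (x.size - 2) // tau - 2
    if feasible < 1:
        raise EmbeddingLengthError(
            f"series of length {x.size} too short for the Cao method at "
            f"tau={tau}"
        )
    max_dim = min(max_dim, feasible)
    # E(m) for m = 1..max_dim+2 -> E1(m), E2(m) for m = 1..max_dim+1
    e = np.empty(max_dim + 2)
    e_star = np.empty(max_dim + 2)
    for m in range(1, max_dim + 3):
        e[m - 1], e_star[m - 1] = _cao_stats(x, tau, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = e[1:] / e[:-1]
        e2 = e_star[1:] / e_star[:-1]
    sat = np.abs(e1 - 1) <= e1_saturation
    for m in range(1, max_dim + 1):
        if sat[m - 1] and sat[m]:
            return CaoResult(dim=m, e1=e1, e2=e2, saturated=True)
    return CaoResult(dim=max_dim, e1=e1, e2=e2, saturated=False)


def majority_vote(candidates: Sequence[int]) -> int:
    """Modal value of a list of parameter candidates; ties -> smallest.

    The low-valued tie-break biases toward less compression, consistent
    with picking the most conservative common parameter across series.
    """
    if len(candidates) == 0:
        raise InsufficientDataError("majority_vote on an empty list")
    counts = Counter(int(c) for c in candidates)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]
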