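"""Diagonal-line entropy of a recurrence matrix and rate scans.

Along every diagonal parallel to the main diagonal (the line of
identity, which is excluded — every state trivially recurs with
itself), maximal runs of recurrent (zero) entries are collected.  The
Shannon entropy (natural log) of the normalised run-length histogram,

    S = - sum_j p_j ln p_j,

estimates the topological entropy of the orbit structure.  S is
scanned over a grid of recurrence rates; the working rate is then
chosen at the breakpoint where the log-log rate-entropy relation stops
being linear — the edge between the detailed and the averaged analysis
regime.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .embedding import EmbeddingParams, embed
from .errors import InsufficientScanError, UndefinedEntropyError
from .recurrence import (
    RecurrenceMatrix,
    lambda_for_rate,
    pairwise_distances,
    recurrence_matrix,
)
from .timeseries import TimeSeries

__all__ = [
    "DiagonalRunHistogram",
    "ScanPoint",
    "EntropyScan",
    "RateSelection",
    "diagonal_runs",
    "shannon_entropy",
    "entropy_scan",
    "select_rate",
]


@dataclass
class DiagonalRunHistogram:
    """Histogram of maximal zero-run lengths along off-main diagonals.

    Both triangles are counted (the matrix is symmetric, so every
    off-diagonal run appears twice); run lengths of 1 are kept.
    """

    counts: dict[int, int]
    excluded_loi: bool = True

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def probabilities(self) -> dict[int, float]:
        t = self.total
        if t == 0:
            raise UndefinedEntropyError("empty run-length histogram")
        return {j: c / t for j, c in sorted(self.counts.items())}


def _zero_run_lengths(vec: np.ndarray) -> list[int]:
    """Lengths of maximal runs of zeros in a 1-d binary vector."""
    zero = np.flatnonzero(vec == 0)
    if zero.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(zero) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [zero.size - 1]))
    return (ends - starts + 1).tolist()


def diagonal_runs(M: RecurrenceMatrix) -> DiagonalRunHistogram:
    """Collect maximal recurrent-run lengths along all off-main diagonals."""
    entries = M.entries
    n = entries.shape[0]
    counts: Counter[int] = Counter()
    for off in range(1, n):
        for diag in (np.diagonal(entries, offset=off),
                     np.diagonal(entries, offset=-off)):
            counts.update(_zero_run_lengths(diag))
    return DiagonalRunHistogram(counts=dict(counts))


def shannon_entropy(hist: DiagonalRunHistogram) -> float:
    """Shannon entropy (nats) of the normalised run-length histogram.

    An empty histogram has no distribution to take the entropy of and
    raises :class:`UndefinedEntropyError` — deliberately distinct from
    the S = 0 of a single-class histogram.
    """
    p = np.array(list(hist.probabilities().values()))
    return float(-np.sum(p * np.log(p)) + 0.0)  # +0.0 avoids -0.0


class ScanPoint(NamedTuple):
    target_rate: float
    achieved_rate: float
    lam: float
    entropy: Optional[float]  # None when the histogram was empty


@dataclass
class EntropyScan:
    """Entropy S over a grid of recurrence rates for one series."""

    points: list[ScanPoint]
    series_label: str = ""

    def valid_points(self) -> list[ScanPoint]:
        """Points with a defined, positive entropy (usable on log axes)."""
        return [p for p in self.points if p.entropy is not None and p.entropy > 0]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pts = self.valid_points()
        return (np.array([p.achieved_rate for p in pts]),
                np.array([p.entropy for p in pts]))


def default_rate_grid(n: int = 30, lo: float = 0.01, hi: float = 1.0) -> np.ndarray:
    """Logarithmically spaced recurrence-rate targets."""
    return np.geomspace(lo, hi, n)


def entropy_scan(
    series: TimeSeries,
    params: EmbeddingParams,
    rate_grid: Optional[Sequence[float]] = None,
    norm: str = "euclidean",
) -> EntropyScan:
    """Scan diagonal-line entropy over a grid of target recurrence rates.

    For each target the threshold comes from the distance-quantile rule,
    so distinct targets can land on the same achieved rate on a discrete
    distance multiset; duplicate achieved rates are dropped (first one
    kept) to keep the scan strictly increasing in rate.
    """
    grid = default_rate_grid() if rate_grid is None else np.asarray(rate_grid, float)
    if np.any(grid <= 0) or np.any(grid > 1) or np.any(np.diff(grid) <= 0):
        raise InsufficientScanError(
            "rate grid must be strictly increasing within (0, 1]"
        )
    emb = embed(series, params)
    dist = pairwise_distances(emb, norm=norm)
    points: list[ScanPoint] = []
    seen: set[float] = set()
    for target in grid:
        thr = lambda_for_rate(dist, float(target))
        if thr.achieved_rate in seen:
            continue
        seen.add(thr.achieved_rate)
        M = recurrence_matrix(dist, thr.lam)
        hist = diagonal_runs(M)
        S = shannon_entropy(hist) if hist.total > 0 else None
        points.append(ScanPoint(float(target), thr.achieved_rate, thr.lam, S))
    return EntropyScan(points=points, series_label=series.label)


@dataclass
class RateSelection:
    """Working recurrence rate voted from per-series scan breakpoints."""

    working_rate: float
    per_scan_rates: list[float]
    no_edge_flags: list[bool]


def _piecewise_sse(x: np.ndarray, y: np.ndarray, xb: float) -> float:
    """SSE of the best continuous two-segment fit with hinge at xb."""
    A = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - xb)])
    _, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if res.size:
        return float(res[0])
    fit = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(np.sum((y - fit) ** 2))


def _line_sse(x: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones_like(x), x])
    fit = A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(np.sum((y - fit) ** 2))


def select_rate(scans: Sequence[EntropyScan], min_points: int = 5) -> RateSelection:
    """Pick the working recurrence rate at the edge of log-log linearity.

    Per scan, on (log rate, log S): every continuous two-segment
    piecewise-linear model with its breakpoint at an interior grid
    point is fitted by least squares; the breakpoint minimising the
    total squared error is that scan's candidate (ties -> smaller
    rate).  When a single line fits as well as the best broken one the
    scan carries no detectable edge and is flagged.  The final rate is
    the modal candidate across scans (ties -> smaller rate).
    """
    if len(scans) == 0:
        raise InsufficientScanError("no scans given")
    per_scan: list[float] = []
    flags: list[bool] = []
    for scan in scans:
        pts = scan.valid_points()
        if len(pts) < min_points:
            raise InsufficientScanError(
                f"scan {scan.series_label!r} has {len(pts)} valid points; "
                f"need >= {min_points}"
            )
        if len(pts) < len(scan.points):
            warnings.warn(
                f"scan {scan.series_label!r}: "
                f"{len(scan.points) - len(pts)} non-positive/missing entropy "
                "points excluded from the log-log fit",
                stacklevel=2,
            )
        x = np.log([p.achieved_rate for p in pts])
        y = np.log([p.entropy for p in pts])
        best_sse, best_idx = np.inf, None
        for b in range(1, len(pts) - 1):
            sse = _piecewise_sse(x, y, x[b])
            if sse < best_sse - 1e-15:
                best_sse, best_idx = sse, b
        sse_line = _line_sse(x, y)
        no_edge = sse_line <= best_sse + 1e-10 * (1.0 + sse_line)
        per_scan.append(pts[best_idx].achieved_rate)
        flags.append(bool(no_edge))
    keyed = Counter(round(r, 12) for r in per_scan)
    best = max(keyed.items(), key=lambda kv: (kv[1], -kv[0]))
    return RateSelection(working_rate=float(best[0]),
                         per_scan_rates=per_scan,
                         no_edge_flags=flags)
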