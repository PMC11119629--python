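"""Model/results interface for the full recurrence-plot analysis.

:class:`RecurrenceAnalysis` bundles one or more interaction-count
series and the analysis settings; :meth:`RecurrenceAnalysis.fit` runs
the whole chain — increments, delay and dimension selection with
majority voting, entropy-vs-rate scans, working-rate selection at the
log-log breakpoint, recurrence matrices at the working rate, and
dark/white cross detection — and returns a
:class:`RecurrenceAnalysisResults` carrying every estimate, a
``summary()`` table, and plotting/export helpers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import crosses as _crosses
from . import embedding as _embedding
from . import recurrence as _recurrence
from . import rqa as _rqa
from .errors import ConfigurationError, InsufficientDataError
from .timeseries import TimeSeries, increments

logger = logging.getLogger("rpcross")

__all__ = ["RecurrenceAnalysis", "RecurrenceAnalysisResults", "SeriesResult"]


@dataclass
class SeriesResult:
    """Per-series estimates at the voted working point."""

    label: str
    tau: int
    dim: int
    cao_noise_flag: bool
    lam: float
    achieved_rate: float
    entropy: Optional[float]
    scan: _rqa.EntropyScan
    matrix: _recurrence.RecurrenceMatrix
    crosses: dict[str, _crosses.CrossDetectionResult]


class RecurrenceAnalysis:
    """Recurrence-plot analysis of one or more interaction-count series.

    Parameters
    ----------
    series : TimeSeries or sequence of TimeSeries
        Input series.  Raw counts are differenced to increments unless
        ``inputs_are_increments`` (or the series' own ``is_increment``
        flag) says they already are; auto-detection is deliberately
        refused.
    inputs_are_increments : bool
        Declare that all inputs are increments even if unflagged.
    alpha : float
        Significance level of the white-noise band for the delay.
    max_dim, e1_saturation : int, float
        Cao-method search cap and E1 saturation tolerance.
    norm : str
        Distance norm for the recurrence matrix.
    rate_grid : array-like, optional
        Recurrence-rate targets for the entropy scan (default: 30
        log-spaced points in [0.01, 1]).
    working_rate : float, optional
        Override the automatic breakpoint selection (e.g. the 0.09 of
        a previous run).
    threshold_sigma : float
        Standard-score threshold for cross centres (default 2.5).
    polarities : sequence of str
        Which cross polarities to detect ("dark", "white").
    k_grid : sequence of int, optional
        Candidate SMA widths (default 1..side//4).
    tau, dim : int, optional
        Fix the embedding parameters instead of estimating them.

    Examples
    --------
    >>> from rpcross.synthetic import toy_vector
    >>> from rpcross.model import RecurrenceAnalysis
    >>> res = RecurrenceAnalysis(toy_vector(), tau=2, dim=1,
    ...                          working_rate=5/9, threshold_sigma=1.0,
    ...                          k_grid=[1]).fit()
    >>> round(res.series_results[0].entropy, 3)
    0.0
    """

    def __init__(
        self,
        series,
        *,
        inputs_are_increments: bool = False,
        alpha: float = 0.05,
        max_dim: int = 10,
        e1_saturation: float = 0.05,
        norm: str = "euclidean",
        rate_grid: Optional[Sequence[float]] = None,
        working_rate: Optional[float] = None,
        threshold_sigma: float = 2.5,
        polarities: Sequence[str] = ("dark",),
        k_grid: Optional[Sequence[int]] = None,
        tau: Optional[int] = None,
        dim: Optional[int] = None,
    ) -> None:
        if isinstance(series, TimeSeries):
            series = [series]
        if len(series) == 0:
            raise InsufficientDataError("need at least one input series")
        self.raw_series: list[TimeSeries] = list(series)
        self.inputs_are_increments = bool(inputs_are_increments)
        self.alpha = float(alpha)
        self.max_dim = int(max_dim)
        self.e1_saturation = float(e1_saturation)
        self.norm = norm
        self.rate_grid = (None if rate_grid is None
                          else np.asarray(rate_grid, dtype=float))
        self.working_rate = working_rate
        self.threshold_sigma = float(threshold_sigma)
        self.polarities = tuple(polarities)
        for pol in self.polarities:
            if pol not in ("dark", "white"):
                raise ConfigurationError(f"unknown polarity {pol!r}")
        self.k_grid = None if k_grid is None else [int(k) for k in k_grid]
        self.fixed_tau = None if tau is None else int(tau)
        self.fixed_dim = None if dim is None else int(dim)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        columns: Optional[Sequence[str]] = None,
        time_column: str = "time",
        **kwargs,
    ) -> "RecurrenceAnalysis":
        """Build an analysis from one series per DataFrame column."""
        dt = 1.0
        if time_column in df.columns:
            steps = np.diff(df[time_column].to_numpy(dtype=float))
            dt = float(np.mean(steps))
        if columns is None:
            columns = [c for c in df.columns if c != time_column]
        inc = kwargs.get("inputs_are_increments", False)
        series = [
            TimeSeries(df[c].to_numpy(dtype=float), dt=dt, label=str(c),
                       is_increment=inc)
            for c in columns
        ]
        return cls(series, **kwargs)

    # -- fitting ------------------------------------------------------

    def _increment_series(self) -> list[TimeSeries]:
        out = []
        for s in self.raw_series:
            if s.is_increment or self.inputs_are_increments:
                out.append(s)
            else:
                out.append(increments(s))
        return out

    def fit(self) -> "RecurrenceAnalysisResults":
        """Run the full analysis chain and return the results object."""
        incs = self._increment_series()

        taus, dims, noise_flags = [], [], []
        for s in incs:
            tau_s = (self.fixed_tau if self.fixed_tau is not None
                     else _embedding.delay_by_autocorrelation(s, alpha=self.alpha))
            if self.fixed_dim is not None:
                dim_s, noisy = self.fixed_dim, False
            else:
                cao = _embedding.cao_dimension(
                    s, tau_s, max_dim=self.max_dim,
                    e1_saturation=self.e1_saturation,
                )
                # Cao identifies the minimal number of coordinates m;
                # the sub-series order is one less (a sub-series has
                # dim + 1 coordinates).
                dim_s, noisy = max(1, cao.dim - 1), cao.noise_flag
            taus.append(tau_s)
            dims.append(dim_s)
            noise_flags.append(noisy)
            logger.info("series %r: tau=%d dim=%d%s", s.label, tau_s, dim_s,
                        " (noise flag)" if noisy else "")

        tau = _embedding.majority_vote(taus)
        dim = _embedding.majority_vote(dims)
        params = _embedding.EmbeddingParams(tau=tau, dim=dim)
        logger.info("voted parameters: tau=%d dim=%d", tau, dim)

        scans = [
            _rqa.entropy_scan(s, params, rate_grid=self.rate_grid, norm=self.norm)
            for s in incs
        ]

        if self.working_rate is not None:
            rate = float(self.working_rate)
            rate_selection = None
        else:
            rate_selection = _rqa.select_rate(scans)
            rate = rate_selection.working_rate
        logger.info("working recurrence rate: %.4g", rate)

        series_results = []
        for s, scan, tau_s, dim_s, noisy in zip(incs, scans, taus, dims, noise_flags):
            emb = _embedding.embed(s, params)
            dist = _recurrence.pairwise_distances(emb, norm=self.norm)
            thr = _recurrence.lambda_for_rate(dist, rate)
            M = _recurrence.recurrence_matrix(dist, thr.lam)
            hist = _rqa.diagonal_runs(M)
            S = _rqa.shannon_entropy(hist) if hist.total > 0 else None
            found = {
                pol: _crosses.detect_crosses(
                    M, threshold_sigma=self.threshold_sigma, polarity=pol,
                    k_grid=self.k_grid,
                )
                for pol in self.polarities
            }
            for pol, det in found.items():
                logger.info(
                    "series %r: lambda=%.6g RR=%.4g S=%s %s crosses=%s (k=%d)",
                    s.label, thr.lam, thr.achieved_rate,
                    f"{S:.4f}" if S is not None else "n/a",
                    pol, det.centers, det.k,
                )
            series_results.append(SeriesResult(
                label=s.label, tau=tau_s, dim=dim_s, cao_noise_flag=noisy,
                lam=thr.lam, achieved_rate=thr.achieved_rate, entropy=S,
                scan=scan, matrix=M, crosses=found,
            ))

        return RecurrenceAnalysisResults(
            model=self, params=params, working_rate=rate,
            rate_selection=rate_selection, series_results=series_results,
            per_series_tau=taus, per_series_dim=dims,
        )


@dataclass
class RecurrenceAnalysisResults:
    """Estimates and diagnostics from :meth:`RecurrenceAnalysis.fit`."""

    model: RecurrenceAnalysis
    params: _embedding.EmbeddingParams
    working_rate: float
    rate_selection: Optional[_rqa.RateSelection]
    series_results: list[SeriesResult]
    per_series_tau: list[int]
    per_series_dim: list[int]

    @property
    def tau(self) -> int:
        return self.params.tau

    @property
    def dim(self) -> int:
        return self.params.dim

    def summary_frame(self) -> pd.DataFrame:
        """Per-series table of estimates."""
        rows = []
        for sr in self.series_results:
            row = {
                "series": sr.label,
                "tau": sr.tau,
                "dim": sr.dim,
                "lambda": sr.lam,
                "rate": sr.achieved_rate,
                "entropy": sr.entropy,
            }
            for pol, det in sr.crosses.items():
                row[f"{pol}_crosses"] = det.n_crosses
                row[f"{pol}_k"] = det.k
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of the fitted analysis."""
        lines = [
            "Recurrence-plot analysis",
            "=" * 60,
            f"series:               {len(self.series_results)}",
            f"voted delay tau:      {self.tau}",
            f"voted order dim:      {self.dim} (sub-series of {self.dim + 1} points)",
            f"working rec. rate:    {self.working_rate:.6g}"
            + ("" if self.rate_selection is None else "  (log-log breakpoint vote)"),
            f"norm:                 {self.model.norm}",
            f"cross threshold:      {self.model.threshold_sigma} sigma",
            "-" * 60,
            self.summary_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------

    def plot_entropy_scan(self, ax=None):
        """Log-log entropy-vs-rate curves with the working rate dashed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sr in self.series_results:
            r, s = sr.scan.to_arrays()
            ax.loglog(r, s, marker="o", ms=3, label=sr.label)
        ax.axvline(self.working_rate, ls="--", color="k")
        ax.set_xlabel("recurrence rate")
        ax.set_ylabel("diagonal-line entropy S (nats)")
        ax.legend(fontsize="small")
        return ax

    def save_recurrence_plots(self, directory, upscale: int = 1) -> list[Path]:
        """Render each recurrence plot (with cross overlays) as PNG."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, sr in enumerate(self.series_results):
            name = sr.label or f"series{i}"
            out = directory / f"rp_{name}.png"
            _recurrence.render_plot(
                sr.matrix, str(out),
                overlays=list(sr.crosses.values()), upscale=upscale,
            )
            paths.append(out)
        return paths

    # -- export -------------------------------------------------------

    def to_report(self) -> dict:
        """Machine-readable report of every estimate."""
        return {
            "voted": {"tau": self.tau, "dim": self.dim,
                      "working_rate": self.working_rate},
            "per_series_tau": self.per_series_tau,
            "per_series_dim": self.per_series_dim,
            "rate_selection": (
                None if self.rate_selection is None else {
                    "per_scan_rates": self.rate_selection.per_scan_rates,
                    "no_edge_flags": self.rate_selection.no_edge_flags,
                }
            ),
            "series": [
                {
                    "label": sr.label,
                    "tau": sr.tau,
                    "dim": sr.dim,
                    "cao_noise_flag": sr.cao_noise_flag,
                    "lambda": sr.lam,
                    "achieved_rate": sr.achieved_rate,
                    "entropy": sr.entropy,
                    "scan": [p._asdict() for p in sr.scan.points],
                    "crosses": {
                        pol: {
                            "k": det.k,
                            "centers": det.centers,
                            "center_scores": det.center_scores,
                            "threshold_sigma": det.threshold_sigma,
                            "no_structure": det.no_structure,
                        }
                        for pol, det in sr.crosses.items()
                    },
                }
                for sr in self.series_results
            ],
        }

    def save_report(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_report(), fh, indent=2, sort_keys=True)
            fh.write("\n")
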