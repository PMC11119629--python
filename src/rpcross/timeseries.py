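"""Labelled, equally spaced interaction-count series and their increments.

The analysis operates on univariate time series of non-covalent
interaction counts N(t) saved at a fixed interval ``dt`` by an MD engine
(e.g. one state every 100 ps).  Raw counts are monotone-ish and carry a
trend; the recurrence analysis instead consumes the increment series
dN/dt, which is quasi-stationary and non-monotonic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    MissingColumnError,
    ParseError,
    SpacingError,
)

__all__ = ["TimeSeries", "increments", "read_series", "write_series"]

#: relative tolerance for the equal-spacing check of a time column
SPACING_RTOL = 1e-6


@dataclass
class TimeSeries:
    """An equally time-spaced scalar series of counts or increments.

    Parameters
    ----------
    values : array-like of float
        The observations, in time order.  Length >= 2, all finite.
    dt : float
        Positive, constant spacing between consecutive samples
        (e.g. 0.1 ns between saved MD states).
    label : str
        Free-text identifier, e.g. ``"HBo@290K"``.
    is_increment : bool
        True when the values are already increments dN/dt rather than
        raw counts.
    """

    values: np.ndarray
    dt: float = 1.0
    label: str = ""
    is_increment: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        # length 1 is tolerated so a 2-point count series can still be
        # differenced; every analysis operation states its own minimum
        if self.values.ndim != 1 or self.values.size < 1:
            raise InsufficientDataError(
                f"series {self.label!r}: need a non-empty 1-d series, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ParseError(
                f"series {self.label!r}: non-finite value at row {bad}"
            )
        self.dt = float(self.dt)
        if not (self.dt > 0):
            raise SpacingError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times t_i = i * dt, starting at 0."""
        return np.arange(self.values.size) * self.dt


def increments(series: TimeSeries) -> TimeSeries:
    """Forward-difference increment series (N(i+1) - N(i)) / dt.

    Output has length L - 1 and ``is_increment=True``.  The downstream
    recurrence pipeline is invariant to the 1/dt scaling because the
    recurrence threshold is set by targeting a recurrence rate.
    """
    if series.is_increment:
        raise InsufficientDataError(
            f"series {series.label!r} is already an increment series"
        )
    if len(series) < 2:
        raise InsufficientDataError("need length >= 2 to difference")
    vals = np.diff(series.values) / series.dt
    label = f"{series.label}_incr" if series.label else "incr"
    return TimeSeries(vals, dt=series.dt, label=label, is_increment=True)


def _sniff_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_series(path: str, column: str) -> TimeSeries:
    """Read one labelled column from a delimited text file.

    The file must have a header row.  A column named ``time`` (if
    present) supplies ``dt`` and must be equally spaced to relative
    tolerance 1e-6; otherwise ``dt = 1``.
    """
    sep = _sniff_sep(str(path))
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    if column not in df.columns:
        raise MissingColumnError(
            f"column {column!r} not in {list(df.columns)} of {path}"
        )
    # cells go through Python's float() so written values read back
    # bit-for-bit (CSV cells carry 17 significant digits)
    vals = np.empty(len(df), dtype=float)
    for row, cell in enumerate(df[column].to_numpy()):
        try:
            vals[row] = float(cell)
        except (TypeError, ValueError):
            raise ParseError(
                f"non-numeric cell in column {column!r} at data row {row}"
            ) from None
    if np.any(np.isnan(vals)):
        row = int(np.flatnonzero(np.isnan(vals))[0])
        raise ParseError(
            f"non-numeric cell in column {column!r} at data row {row}"
        )
    dt = 1.0
    if "time" in df.columns:
        t = pd.to_numeric(df["time"], errors="coerce")
        if t.isna().any():
            row = int(np.flatnonzero(t.isna().to_numpy())[0])
            raise ParseError(f"non-numeric cell in time column at data row {row}")
        t = t.to_numpy(dtype=float)
        if t.size >= 2:
            steps = np.diff(t)
            dt = float(np.mean(steps))
            if dt <= 0 or np.any(
                np.abs(steps - dt) > SPACING_RTOL * max(abs(dt), 1e-300)
            ):
                raise SpacingError(
                    f"time column of {path} is not equally spaced "
                    f"(steps range {steps.min()}..{steps.max()})"
                )
    return TimeSeries(vals, dt=dt, label=column)


def write_series(series: TimeSeries, path: str) -> None:
    """Write a series as CSV with a ``time`` column reconstructed from dt.

    ``read_series(path, series.label)`` inverts this exactly (values,
    dt and label round-trip; float cells are written with repr precision).
    """
    label = series.label or "value"
    df = pd.DataFrame({"time": series.times, label: series.values})
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
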