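"""Seeded synthetic fixtures with the statistical shape the pipeline assumes.

No MD trajectories ship with the package, so every stage is exercised
on generated series that mimic the observables: noisy, quasi-stationary
increment series; saturating count trajectories (fast early aggregation
then a plateau, integer counts on top); series with one anomalous
window (shifted/inflated increments -> dark cross); series with a
stable-oscillation window (low-variance periodic increments -> white
region); and chaotic-map / harmonic series for embedding-parameter
tests.  All randomness flows through ``numpy.random.default_rng(seed)``
(PCG64), so an identical spec reproduces an identical series
bit-for-bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, NamedTuple, Optional

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigurationError
from .timeseries import TimeSeries

__all__ = ["SyntheticSpec", "SyntheticSeries", "toy_vector", "generate"]

KINDS = (
    "toy",
    "iid_noise",
    "ar1",
    "logistic_map",
    "sine",
    "regime_change",
    "oscillation_window",
    "md_like_counts",
)

#: count regimes of the three interaction types (mean level, fluctuation
#: sigma) matching the order of magnitude of the analysed MD systems:
#: ~100 polysaccharide-polysaccharide hydrogen bonds, ~9000
#: polysaccharide-water hydrogen bonds, ~67 hydrophobic-polar contacts.
MD_PRESETS = {
    "hbo": {"mean_level": 115.0, "noise_sigma": 10.0},
    "pw_hbo": {"mean_level": 9000.0, "noise_sigma": 80.0},
    "hp": {"mean_level": 67.0, "noise_sigma": 8.0},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one reproducible synthetic series."""

    kind: str
    length: int = 1000
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(
                f"unknown synthetic kind {self.kind!r}; choose from {KINDS}"
            )


class SyntheticSeries(NamedTuple):
    """Generated series plus ground-truth annotations (None if none)."""

    series: TimeSeries
    truth: Optional[dict]


def toy_vector() -> TimeSeries:
    """The 5-point worked-example vector (1, 1/2, 1, 1/2, 1), dt = 1.

    Flagged as an increment series: it is fed to the analysis as-is,
    never differenced.
    """
    return TimeSeries(np.array([1.0, 0.5, 1.0, 0.5, 1.0]), dt=1.0, label="toy",
                      is_increment=True)


def _window(spec: SyntheticSpec, p: dict) -> tuple[int, int]:
    L = spec.length
    start = int(p.get("window_start", round(0.4 * L)))
    width = int(p.get("window_width", round(0.1 * L)))
    if width < 1 or start < 0 or start + width > L:
        raise ConfigurationError(
            f"window [{start}, {start + width}) does not fit length {L}"
        )
    return start, width


def generate(spec: SyntheticSpec) -> SyntheticSeries:
    """Generate a seeded series of the requested kind.

    Kind-specific ``params`` (all optional):

    - ``iid_noise``: ``mean`` (0), ``sigma`` (1)
    - ``ar1``: ``phi`` (0.5), ``sigma`` (1); ``phi=0`` reproduces
      ``iid_noise`` with the same seed exactly
    - ``logistic_map``: ``r`` (4.0), ``x0`` (0.2)
    - ``sine``: ``period`` (100 samples), ``amplitude`` (1),
      ``noise_sigma`` (0), ``phase`` (0)
    - ``regime_change``: background N(0, sigma) increments with one
      window of mean shift ``shift_sigma`` (4, in background-sigma
      units) and variance inflation ``var_factor`` (1);
      ``window_start`` (0.4 L), ``window_width`` (0.1 L)
    - ``oscillation_window``: background N(0, sigma) increments; the
      window is a stable oscillation around the mean — amplitude
      ``osc_amplitude`` (0.5 sigma), period ``osc_period`` (10),
      residual noise ``osc_noise`` (0.1 sigma)
    - ``md_like_counts``: non-negative integer counts rising to a
      plateau, ``interaction`` preset in {'hbo', 'pw_hbo', 'hp'} or
      explicit ``mean_level``/``noise_sigma``; ``t0`` (L / 10) sets the
      aggregation timescale, ``phi`` (0.7) the fluctuation memory,
      ``dt`` (0.1, ns between saved states)
    """
    p = dict(spec.params)
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    dt = float(p.get("dt", 1.0))
    truth: Optional[dict] = None
    label = p.get("label", spec.kind)
    is_increment = True

    if spec.kind == "toy":
        return SyntheticSeries(toy_vector(), None)

    if spec.kind == "iid_noise":
        x = rng.normal(size=L) * p.get("sigma", 1.0) + p.get("mean", 0.0)

    elif spec.kind == "ar1":
        phi = float(p.get("phi", 0.5))
        e = rng.normal(size=L) * p.get("sigma", 1.0)
        x = lfilter([1.0], [1.0, -phi], e)

    elif spec.kind == "logistic_map":
        r = float(p.get("r", 4.0))
        x0 = float(p.get("x0", 0.2))
        x = np.empty(L)
        x[0] = x0
        for i in range(1, L):
            x[i] = r * x[i - 1] * (1.0 - x[i - 1])

    elif spec.kind == "sine":
        period = float(p.get("period", 100.0))
        amp = float(p.get("amplitude", 1.0))
        phase = float(p.get("phase", 0.0))
        t = np.arange(L)
        x = amp * np.sin(2 * np.pi * t / period + phase)
        ns = float(p.get("noise_sigma", 0.0))
        if ns > 0:
            x = x + rng.normal(size=L) * ns

    elif spec.kind == "regime_change":
        sigma = float(p.get("sigma", 1.0))
        start, width = _window(spec, p)
        shift = float(p.get("shift_sigma", 4.0)) * sigma
        var_factor = float(p.get("var_factor", 1.0))
        x = rng.normal(size=L) * sigma
        x[start:start + width] = x[start:start + width] * np.sqrt(var_factor) + shift
        truth = {"window_start": start, "window_end": start + width,
                 "window_mid": start + width // 2,
                 "shift_sigma": shift / sigma, "var_factor": var_factor}

    elif spec.kind == "oscillation_window":
        sigma = float(p.get("sigma", 1.0))
        start, width = _window(spec, p)
        amp = float(p.get("osc_amplitude", 0.5)) * sigma
        period = float(p.get("osc_period", 10.0))
        res = float(p.get("osc_noise", 0.1)) * sigma
        x = rng.normal(size=L) * sigma
        t = np.arange(width)
        x[start:start + width] = (amp * np.sin(2 * np.pi * t / period)
                                  + rng.normal(size=width) * res)
        truth = {"window_start": start, "window_end": start + width,
                 "window_mid": start + width // 2,
                 "osc_amplitude": amp / sigma, "osc_period": period}

    elif spec.kind == "md_like_counts":
        preset = MD_PRESETS.get(p.get("interaction", "hbo"), MD_PRESETS["hbo"])
        mean_level = float(p.get("mean_level", preset["mean_level"]))
        noise_sigma = float(p.get("noise_sigma", preset["noise_sigma"]))
        t0 = float(p.get("t0", L / 10.0))
        phi = float(p.get("phi", 0.7))
        dt = float(p.get("dt", 0.1))
        t = np.arange(L)
        trend = mean_level * (1.0 - np.exp(-t / t0))
        e = rng.normal(size=L) * noise_sigma * np.sqrt(1.0 - phi**2)
        fluct = lfilter([1.0], [1.0, -phi], e)
        x = np.maximum(0.0, np.round(trend + fluct))
        is_increment = False

    else:  # pragma: no cover - guarded by SyntheticSpec
        raise ConfigurationError(f"unknown kind {spec.kind!r}")

    series = TimeSeries(np.asarray(x, float), dt=dt, label=label,
                        is_increment=is_increment)
    return SyntheticSeries(series, truth)
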