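"""Recurrence matrix construction, rate-targeted thresholding, rendering.

From the delay sub-series, a binary matrix M(lambda) is built with

    m[i, i'] = 0  if  ||y_i - y_i'|| <= lambda,   1 otherwise.

Note the inverted convention relative to most recurrence-plot software:
here 0 marks a recurrence (rendered white) and 1 a non-recurrence
(rendered black).  The *recurrence rate* is the fraction of zeros over
all entries, main diagonal included.  Because no universally accepted
rule fixes lambda, the threshold is set empirically by targeting a
recurrence rate through the quantile of the pairwise-distance multiset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy.spatial.distance import pdist, squareform

from .embedding import EmbeddedSeries, EmbeddingParams
from .errors import ConfigurationError

__all__ = [
    "DistanceMatrix",
    "RecurrenceMatrix",
    "RateThreshold",
    "pairwise_distances",
    "recurrence_matrix",
    "lambda_for_rate",
    "render_plot",
]

_NORMS = {
    "euclidean": "euclidean",
    "max": "chebyshev",
    "chebyshev": "chebyshev",
    "manhattan": "cityblock",
}


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise sub-series distances."""

    entries: np.ndarray
    norm_name: str
    params: Optional[EmbeddingParams] = None
    label: str = ""

    @property
    def side(self) -> int:
        return self.entries.shape[0]


@dataclass
class RecurrenceMatrix:
    """Binary recurrence matrix, 0 = recurrent (within lambda).

    ``recurrence_rate`` counts zeros over all side**2 entries, the main
    diagonal included (every state trivially recurs with itself).
    """

    entries: np.ndarray
    lam: float
    recurrence_rate: float
    norm_name: str
    params: Optional[EmbeddingParams] = None
    label: str = ""

    @property
    def side(self) -> int:
        return self.entries.shape[0]


class RateThreshold(NamedTuple):
    """Threshold lambda achieving (at least) a target recurrence rate."""

    lam: float
    achieved_rate: float
    clamped: bool


def pairwise_distances(emb: EmbeddedSeries, norm: str = "euclidean") -> DistanceMatrix:
    """All pairwise distances between embedded sub-series.

    ``norm`` is one of ``euclidean`` (default), ``max``/``chebyshev``,
    ``manhattan``.
    """
    if norm not in _NORMS:
        raise ConfigurationError(
            f"unknown norm {norm!r}; choose from {sorted(_NORMS)}"
        )
    if emb.n_rows < 2:
        raise ConfigurationError("need at least 2 embedded rows")
    d = squareform(pdist(emb.rows, metric=_NORMS[norm]))
    return DistanceMatrix(entries=d, norm_name=norm, params=emb.params, label=emb.label)


def recurrence_matrix(dist: DistanceMatrix, lam: float) -> RecurrenceMatrix:
    """Threshold a distance matrix into the binary recurrence matrix."""
    if lam < 0:
        raise ConfigurationError(f"lambda must be >= 0, got {lam}")
    entries = (dist.entries > lam).astype(np.uint8)
    n = entries.shape[0]
    rate = float(np.count_nonzero(entries == 0)) / (n * n)
    return RecurrenceMatrix(
        entries=entries,
        lam=float(lam),
        recurrence_rate=rate,
        norm_name=dist.norm_name,
        params=dist.params,
        label=dist.label,
    )


def lambda_for_rate(dist: DistanceMatrix, target_rate: float) -> RateThreshold:
    """Smallest threshold whose recurrence rate reaches ``target_rate``.

    The threshold is the empirical quantile of the full entry multiset
    (diagonal zeros included, consistent with the rate definition).
    The achieved rate is >= target, with equality whenever the target
    is attainable on the discrete multiset.  Targets below the
    attainable minimum (the always-recurrent diagonal) are clamped with
    a warning.
    """
    if not (0 < target_rate <= 1):
        raise ConfigurationError(f"target_rate must be in (0, 1], got {target_rate}")
    flat = np.sort(dist.entries, axis=None)
    n2 = flat.size
    k = max(1, math.ceil(target_rate * n2 - 1e-9))
    lam = float(flat[k - 1])
    achieved = float(np.searchsorted(flat, lam, side="right")) / n2
    clamped = False
    min_rate = float(np.searchsorted(flat, 0.0, side="right")) / n2
    if target_rate < min_rate - 1e-12:
        clamped = True
        warnings.warn(
            f"target rate {target_rate} below attainable minimum {min_rate}; "
            f"clamped to lambda=0",
            stacklevel=2,
        )
    return RateThreshold(lam=lam, achieved_rate=achieved, clamped=clamped)


def render_plot(
    M: RecurrenceMatrix,
    path: str,
    overlays: Optional[Sequence] = None,
    upscale: int = 1,
    invert: bool = False,
) -> None:
    """Write the recurrence plot as a PNG, one pixel per matrix entry.

    1 -> black, 0 -> white (the package's inverted recurrence
    convention); sub-series 1 sits at the top-left and the main
    diagonal runs to the bottom-right.  ``invert`` flips the rendering
    colours only — it never touches analysis.  ``overlays`` takes cross
    annotations (objects with 1-based ``centers`` and width ``k``, see
    :mod:`rpcross.crosses`) drawn as green bounding lines around each
    cross band.
    """
    if upscale < 1:
        raise ConfigurationError(f"upscale must be >= 1, got {upscale}")
    entries = M.entries
    if invert:
        entries = 1 - entries
    # 1 -> 0 (black), 0 -> 255 (white)
    gray = ((1 - entries) * 255).astype(np.uint8)
    if upscale > 1:
        gray = np.kron(gray, np.ones((upscale, upscale), dtype=np.uint8))
    img = Image.fromarray(gray, mode="L").convert("RGB")
    if overlays:
        draw = ImageDraw.Draw(img)
        side = M.side * upscale
        green = (0, 200, 0)
        for res in overlays:
            k = getattr(res, "k", 1) or 1
            for center in getattr(res, "centers", []):
                c0 = int(center) - 1  # 1-based sub-series index -> pixel row
                lo = max(0, c0 - (k - 1) // 2) * upscale
                hi = min(M.side, c0 + k // 2 + 1) * upscale - 1
                # vertical band boundaries
                draw.line([(lo, 0), (lo, side - 1)], fill=green)
                draw.line([(hi, 0), (hi, side - 1)], fill=green)
                # horizontal band boundaries
                draw.line([(0, lo), (side - 1, lo)], fill=green)
                draw.line([(0, hi), (side - 1, hi)], fill=green)
    img.save(path, format="PNG")
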