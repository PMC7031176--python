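"""Time-domain HRV metrics: mean NN/HR, SDNN, CV, Poincaré SD1/SD2.

Mean HR is defined as 60000 / mean NN (not the mean of instantaneous
per-beat rates) and SDNN uses the sample (n-1) standard deviation; both
choices are fixed so exact-value tests are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError
from .io import RRSeries

MIN_INTERVALS = 30


@dataclass(frozen=True)
class TimeDomainSummary:
    mean_nn: float  # ms
    mean_hr: float  # bpm
    sdnn: float  # ms
    cv: float  # percent
    sd1: float  # ms
    sd2: float  # ms
    n_beats: int


def summarize_time_domain(rr: RRSeries) -> TimeDomainSummary:
    """Compute mean NN/HR, SDNN, CV and Poincaré axes of a cleaned series."""
    nn = rr.nn
    if nn.size < MIN_INTERVALS:
        raise InsufficientDataError(
            f"time-domain summary needs >= {MIN_INTERVALS} intervals, got {nn.size}"
        )
    mean_nn = float(np.mean(nn))
    sdnn = float(np.std(nn, ddof=1))
    sd1, sd2, _ = poincare(rr)
    return TimeDomainSummary(
        mean_nn=mean_nn,
        mean_hr=60000.0 / mean_nn,
        sdnn=sdnn,
        cv=100.0 * sdnn / mean_nn,
        sd1=sd1,
        sd2=sd2,
        n_beats=int(nn.size),
    )


def poincare(rr: RRSeries) -> tuple[float, float, np.ndarray]:
    """Poincaré descriptors of the (NN_i, NN_{i+1}) scatter.

    Returns ``(sd1, sd2, points)`` where ``sd1 = sqrt(var(diff(NN)) / 2)``
    and ``sd2 = sqrt(max(2 var(NN) - sd1**2, 0))``, so the identity
    ``sd1**2 + sd2**2 == 2 var(NN)`` holds whenever sd2 is not clamped.
    """
    nn = rr.nn
    if nn.size < 3:
        raise InsufficientDataError("poincare needs >= 3 intervals")
    d = np.diff(nn)
    sd1_sq = np.var(d, ddof=1) / 2.0
    sd2_sq = 2.0 * np.var(nn, ddof=1) - sd1_sq
    points = np.column_stack((nn[:-1], nn[1:]))
    return float(np.sqrt(sd1_sq)), float(np.sqrt(max(sd2_sq, 0.0))), points
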