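"""Frequency-domain HRV: even resampling, Welch PSD, temperature-adjusted bands.

The VLF/LF/HF cut-offs shift with ambient temperature to track the beating
rate: at 20 °C the bands are 0-0.5 / 0.5-1.5 / 1.5-5.0 Hz, at 30 °C
0-0.2 / 0.2-0.75 / 0.75-3.0 Hz.  Band assignment of a fixed modulation
frequency therefore depends only on the active scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .exceptions import ConfigurationError, InsufficientDataError, ValidationError
from .io import RRSeries

MIN_SPAN_S = 60.0


@dataclass(frozen=True)
class BandScheme:
    """Frequency cut-offs (Hz) for the VLF / LF / HF bands."""

    label: str
    vlf: tuple[float, float]
    lf: tuple[float, float]
    hf: tuple[float, float]

    def __post_init__(self) -> None:
        edges = (self.vlf[0], self.vlf[1], self.lf[1], self.hf[1])
        if not (0 <= edges[0] < edges[1] < edges[2] < edges[3]):
            raise ValidationError(f"band edges must be increasing, got {edges}")
        if self.vlf[1] != self.lf[0] or self.lf[1] != self.hf[0]:
            raise ValidationError("bands must be contiguous (vlf.hi==lf.lo, lf.hi==hf.lo)")


SCHEME_20C = BandScheme("20C", vlf=(0.0, 0.5), lf=(0.5, 1.5), hf=(1.5, 5.0))
SCHEME_30C = BandScheme("30C", vlf=(0.0, 0.2), lf=(0.2, 0.75), hf=(0.75, 3.0))

SCHEMES = {"20C": SCHEME_20C, "30C": SCHEME_30C}


def scheme_for_temperature(temperature: str) -> BandScheme:
    try:
        return SCHEMES[temperature]
    except KeyError:
        raise ConfigurationError(
            f"no band scheme for temperature {temperature!r}; known: {sorted(SCHEMES)}"
        ) from None


@dataclass
class UniformSignal:
    """NN series resampled onto a uniform time grid (values in ms)."""

    values: np.ndarray
    rate: float  # Hz
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate


@dataclass
class SpectralEstimate:
    frequencies: np.ndarray  # Hz, uniform, starting at 0
    psd: np.ndarray  # ms^2 / Hz
    resample_rate: float
    segment_length: float  # s
    overlap: float
    window: str = "hann"

    @property
    def nyquist(self) -> float:
        return self.resample_rate / 2.0

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass(frozen=True)
class BandPowers:
    total: float  # ms^2
    vlf: float
    lf: float
    hf: float


def resample_evenly(rr: RRSeries, rate: float = 20.0) -> UniformSignal:
    """Cubic-spline interpolation of (onset time, NN) on a uniform grid.

    Cleaning gaps are bridged by the spline.  Requires a span of at least
    60 s between first and last valid interval onsets.
    """
    t = rr.onset_times
    x = rr.nn
    if t.size < 4 or t[-1] - t[0] < MIN_SPAN_S:
        raise InsufficientDataError(
            f"resampling needs a span of >= {MIN_SPAN_S:.0f} s of valid beats"
        )
    spline = CubicSpline(t, x)
    n = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return UniformSignal(values=spline(grid), rate=rate, t0=float(t[0]))


def estimate_psd(
    signal: UniformSignal,
    segment_s: float = 60.0,
    overlap: float = 0.5,
    window: str = "hann",
    detrend: str = "linear",
) -> SpectralEstimate:
    """Welch PSD (density scaling, ms^2/Hz) of the resampled NN signal."""
    nperseg = int(round(segment_s * signal.rate))
    noverlap = int(round(nperseg * overlap))
    min_len = nperseg + (nperseg - noverlap)  # two overlapping segments
    if signal.values.size < min_len:
        raise InsufficientDataError(
            f"Welch needs >= 2 segments ({min_len} samples at "
            f"{segment_s:.0f} s / {overlap:.0%} overlap), got {signal.values.size}"
        )
    f, pxx = sps.welch(
        signal.values,
        fs=signal.rate,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=detrend,
        scaling="density",
    )
    return SpectralEstimate(
        frequencies=f,
        psd=pxx,
        resample_rate=signal.rate,
        segment_length=segment_s,
        overlap=overlap,
        window=window,
    )


def _band_integral(spec: SpectralEstimate, low: float, high: float, skip_dc: bool) -> float:
    """Trapezoidal integral of the PSD over [low, high].

    Adjacent bands share their boundary bin; with the trapezoid rule the
    shared bin contributes half its weight to each side, so summing
    contiguous bands reproduces the integral over their union exactly.
    """
    f = spec.frequencies
    mask = (f >= low - 1e-12) & (f <= high + 1e-12)
    if skip_dc:
        mask &= f > 0
    idx = np.nonzero(mask)[0]
    if idx.size < 2:
        return 0.0
    return float(np.trapezoid(spec.psd[idx], f[idx]))


def band_powers(spec: SpectralEstimate, scheme: BandScheme) -> BandPowers:
    """Integrate the PSD over the scheme's VLF/LF/HF bands.

    The DC bin is excluded from VLF (and hence from total); total is defined
    as vlf + lf + hf so conservation holds exactly.
    """
    if scheme.hf[1] > spec.nyquist + 1e-9:
        raise ConfigurationError(
            f"HF upper cut-off {scheme.hf[1]} Hz exceeds Nyquist {spec.nyquist} Hz; "
            "increase the resample rate"
        )
    vlf = _band_integral(spec, scheme.vlf[0], scheme.vlf[1], skip_dc=True)
    lf = _band_integral(spec, scheme.lf[0], scheme.lf[1], skip_dc=False)
    hf = _band_integral(spec, scheme.hf[0], scheme.hf[1], skip_dc=False)
    return BandPowers(total=vlf + lf + hf, vlf=vlf, lf=lf, hf=hf)
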