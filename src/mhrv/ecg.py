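"""R-peak detection and RR artifact cleaning.

The detector is a derivative-energy scheme: the squared first difference is
smoothed with a short moving average and thresholded against a rolling
median + k*MAD, with an enforced refractory period.  Cleaning is a
range + running-median screen; removed intervals are dropped (masked), not
interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .exceptions import CleaningError, InsufficientDataError, NoPeaksError, ValidationError
from .io import ECGRecord, RRSeries

logger = logging.getLogger("mhrv")

DEFAULT_REFRACTORY_MS = 30.0
CLEAN_MIN_MS = 50.0
CLEAN_MAX_MS = 350.0
CLEAN_MAX_REL_DEV = 0.3
RUNNING_MEDIAN_BEATS = 9
WARN_EXCLUSION = 0.05
MAX_EXCLUSION = 0.20


@dataclass
class PeakTrain:
    peak_times: np.ndarray  # s, strictly increasing
    detection_threshold_trace: np.ndarray  # per-window threshold values

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValidationError("peak times must be strictly increasing")


def detect_rpeaks(ecg: ECGRecord, refractory_ms: float = DEFAULT_REFRACTORY_MS) -> PeakTrain:
    """Detect R-peaks in a single-lead ECG.

    Requires fs >= 250 Hz and >= 5 s of signal.  Peak locations are refined
    to the local maximum of the lightly smoothed trace, which places them at
    the QRS apex to within ~1 sample.
    """
    if ecg.sampling_rate < 250:
        raise ValidationError("detect_rpeaks requires sampling_rate >= 250 Hz")
    if ecg.duration < 5.0:
        raise InsufficientDataError("detect_rpeaks requires >= 5 s of ECG")
    x = ecg.samples
    if np.var(x) == 0:
        raise NoPeaksError("flat ECG signal (zero variance)")
    fs = ecg.sampling_rate
    refractory = max(1, int(round(refractory_ms / 1000.0 * fs)))

    # pre-smooth (~4 ms) to limit the noise bandwidth before differencing
    pre = uniform_filter1d(x, max(3, int(round(0.004 * fs))))
    energy = np.gradient(pre) ** 2
    smooth_win = max(3, int(round(0.008 * fs)))
    feature = uniform_filter1d(energy, smooth_win)

    # rolling-window threshold: median + 8 * MAD per 2-s window
    win = max(smooth_win, int(round(2.0 * fs)))
    nwin = int(np.ceil(feature.size / win))
    thresholds = np.empty(nwin)
    thr = np.empty_like(feature)
    for w in range(nwin):
        seg = feature[w * win:(w + 1) * win]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        thresholds[w] = med + 8.0 * mad
        thr[w * win:(w + 1) * win] = thresholds[w]

    idx, _ = find_peaks(feature, height=thr, distance=refractory)
    if idx.size == 0:
        raise NoPeaksError("no peaks above the adaptive threshold")

    # refine to the apex of the (lightly smoothed) raw trace
    refine_half = max(1, int(round(0.005 * fs)))
    smooth_x = uniform_filter1d(x, max(3, int(round(0.003 * fs))))
    refined = np.empty(idx.size, dtype=int)
    for i, p in enumerate(idx):
        lo = max(0, p - refine_half)
        hi = min(x.size, p + refine_half + 1)
        refined[i] = lo + int(np.argmax(smooth_x[lo:hi]))
    refined = np.unique(refined)
    # re-enforce refractory after refinement
    keep = [refined[0]]
    for p in refined[1:]:
        if p - keep[-1] >= refractory:
            keep.append(p)
    times = np.asarray(keep, dtype=float) / fs
    return PeakTrain(peak_times=times, detection_threshold_trace=thresholds)


def rr_from_peaks(peaks: PeakTrain, animal_id: str = "") -> RRSeries:
    """Successive peak-time differences as an (uncleaned) RR series."""
    if peaks.peak_times.size < 2:
        raise InsufficientDataError("need >= 2 peaks to form intervals")
    return RRSeries.from_beat_times(peaks.peak_times, animal_id=animal_id)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def clean_rr(
    rr: RRSeries,
    min_ms: float = CLEAN_MIN_MS,
    max_ms: float = CLEAN_MAX_MS,
    max_rel_dev: float = CLEAN_MAX_REL_DEV,
) -> RRSeries:
    """Mask artifact intervals: outside [min_ms, max_ms] or deviating more
    than ``max_rel_dev`` from the 9-beat running median of currently valid
    intervals.

    Returns a new series with ``cleaned=True``.  Exclusion above 5 % sets
    ``high_exclusion`` (and logs a warning); above 20 % raises
    :class:`CleaningError`.
    """
    x = rr.intervals[rr.valid]
    in_range = (x >= min_ms) & (x <= max_ms)
    med = _running_median(x, RUNNING_MEDIAN_BEATS)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(x - med) / med
    ok = in_range & (rel <= max_rel_dev)
    new_valid = rr.valid.copy()
    new_valid[np.nonzero(rr.valid)[0][~ok]] = False
    out = rr.replace(valid=new_valid, cleaned=True)
    frac = out.exclusion_fraction
    # the fraction rule is only meaningful for series long enough to analyse
    if frac > MAX_EXCLUSION and out.n_raw >= 30:
        raise CleaningError(
            f"cleaning would exclude {frac:.1%} of intervals (> {MAX_EXCLUSION:.0%})"
        )
    if frac > WARN_EXCLUSION:
        logger.warning(
            "%s: cleaning excluded %.1f%% of intervals", rr.animal_id, 100 * frac
        )
        out.high_exclusion = True
    if frac > 0:
        logger.info("%s: excluded %d/%d intervals", rr.animal_id, out.n_raw - out.n_clean, out.n_raw)
    return out
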