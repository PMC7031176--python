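"""Reading and writing of RR series, ECG traces, cohort manifests and metric tables.

Units convention (used throughout the package): beat times are seconds from
recording start, intervals are milliseconds, metric outputs are ms / ms**2 /
bpm.  CSV is the canonical interchange format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ParseError, ValidationError

logger = logging.getLogger("mhrv")

AGE_GROUPS = ("young", "old")
TEMPERATURES = ("20C", "30C")
STATES = ("basal", "intrinsic")

#: Flat metric columns written by :func:`write_hrv_table`, in order.
METRIC_COLUMNS = [
    "n_beats",
    "mean_nn_ms",
    "mean_hr_bpm",
    "sdnn_ms",
    "cv_pct",
    "sd1_ms",
    "sd2_ms",
    "total_power_ms2",
    "vlf_ms2",
    "lf_ms2",
    "hf_ms2",
    "beta",
    "mse",
    "dfa_alpha",
    "hurst",
]


@dataclass
class RRSeries:
    """An ordered beat/interval series with provenance and cleaning state.

    ``beat_times`` has one more element than ``intervals`` and
    ``intervals[i] == (beat_times[i+1] - beat_times[i]) * 1000``.  Cleaning
    never re-times beats: it marks intervals invalid through ``valid`` so the
    original point process is preserved.
    """

    beat_times: np.ndarray  # seconds, strictly increasing, length n + 1
    intervals: np.ndarray  # milliseconds, length n
    animal_id: str = ""
    valid: np.ndarray = field(default=None)  # bool mask over intervals
    cleaned: bool = False
    high_exclusion: bool = False  # set when cleaning removed > 5 %

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.intervals.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.intervals.size != self.beat_times.size - 1:
            raise ValidationError(
                "intervals must have length len(beat_times) - 1 "
                f"(got {self.intervals.size} vs {self.beat_times.size} beats)"
            )
        if self.intervals.size and not np.all(self.intervals > 0):
            raise ValidationError("all intervals must be positive")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat times must be strictly increasing")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_beat_times(cls, beat_times: Sequence[float], animal_id: str = "") -> "RRSeries":
        t = np.asarray(beat_times, dtype=float)
        return cls(beat_times=t, intervals=np.diff(t) * 1000.0, animal_id=animal_id)

    @classmethod
    def from_intervals(cls, nn_ms: Sequence[float], animal_id: str = "") -> "RRSeries":
        nn = np.asarray(nn_ms, dtype=float)
        t = np.concatenate(([0.0], np.cumsum(nn) / 1000.0))
        return cls(beat_times=t, intervals=nn, animal_id=animal_id)

    # -- views ------------------------------------------------------------
    @property
    def nn(self) -> np.ndarray:
        """Valid (normal-to-normal) intervals in ms."""
        return self.intervals[self.valid]

    @property
    def onset_times(self) -> np.ndarray:
        """Onset time (s) of each valid interval."""
        return self.beat_times[:-1][self.valid]

    @property
    def n_raw(self) -> int:
        return int(self.intervals.size)

    @property
    def n_clean(self) -> int:
        return int(self.valid.sum())

    @property
    def exclusion_fraction(self) -> float:
        if self.n_raw == 0:
            return 0.0
        return 1.0 - self.n_clean / self.n_raw

    @property
    def span(self) -> float:
        """Time (s) from first to last beat."""
        return float(self.beat_times[-1] - self.beat_times[0])

    def replace(self, **kw) -> "RRSeries":
        params = dict(
            beat_times=self.beat_times,
            intervals=self.intervals,
            animal_id=self.animal_id,
            valid=self.valid,
            cleaned=self.cleaned,
            high_exclusion=self.high_exclusion,
        )
        params.update(kw)
        return RRSeries(**params)


@dataclass
class ECGRecord:
    """Single-lead ECG trace."""

    sampling_rate: float  # Hz
    samples: np.ndarray  # voltage, arbitrary units (nominally mV)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class ManifestEntry:
    animal_id: str
    age_group: str
    temperature: str
    state: str
    path: str


@dataclass
class CohortManifest:
    """Validated assignment of recordings to the 2x2x2 study design."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        seen = {}
        ages = {}
        for i, e in enumerate(self.entries):
            if e.age_group not in AGE_GROUPS:
                raise ValidationError(
                    f"unknown age_group {e.age_group!r}; allowed: {AGE_GROUPS}"
                )
            if e.temperature not in TEMPERATURES:
                raise ValidationError(
                    f"unknown temperature {e.temperature!r}; allowed: {TEMPERATURES}"
                )
            if e.state not in STATES:
                raise ValidationError(
                    f"unknown state {e.state!r}; allowed: {STATES}"
                )
            key = (e.animal_id, e.temperature, e.state)
            if key in seen:
                raise ValidationError(f"duplicate manifest key {key} at row {i + 2}")
            seen[key] = i
            if e.animal_id in ages and ages[e.animal_id] != e.age_group:
                raise ValidationError(
                    f"animal {e.animal_id!r} has inconsistent age_group"
                )
            ages[e.animal_id] = e.age_group

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_rr(path: str | Path, animal_id: str = "") -> RRSeries:
    """Read an RR CSV.

    Accepted layouts: ``time_s,nn_ms`` (interval onset times + intervals,
    the format :func:`write_rr` emits), a lone ``time_s`` column of beat
    times (intervals derived by differencing), or a lone ``nn_ms`` column
    (beat times reconstructed cumulatively from 0).  Row numbers in errors
    count data rows from 1.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "time_s" in cols:
        t = df["time_s"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise ParseError(
                f"{path}: beat times not strictly increasing at row {bad[0] + 2}"
            )
        if "nn_ms" in cols and df["nn_ms"].notna().all():
            nn = df["nn_ms"].to_numpy(dtype=float)
            bad = np.nonzero(nn <= 0)[0]
            if bad.size:
                raise ParseError(f"{path}: non-positive interval at row {bad[0] + 1}")
            return _rr_from_onsets(t, nn, animal_id or path.stem, path)
        return RRSeries.from_beat_times(t, animal_id=animal_id or path.stem)
    if "nn_ms" in cols:
        nn = df["nn_ms"].to_numpy(dtype=float)
        bad = np.nonzero(nn <= 0)[0]
        if bad.size:
            raise ParseError(f"{path}: non-positive interval at row {bad[0] + 1}")
        return RRSeries.from_intervals(nn, animal_id=animal_id or path.stem)
    raise ParseError(f"{path}: expected 'time_s,nn_ms' or 'nn_ms' columns, got {cols}")


def _rr_from_onsets(t: np.ndarray, nn: np.ndarray, animal_id: str, path: Path) -> RRSeries:
    """Build a series from interval onset times + intervals (write_rr's layout).

    The final beat time is the last onset plus its interval; the stored
    intervals are taken verbatim so the write/read round trip is exact.
    """
    gaps = t[1:] - (t[:-1] + nn[:-1] / 1000.0)
    if np.any(gaps < -1e-6):
        row = int(np.nonzero(gaps < -1e-6)[0][0]) + 1
        raise ParseError(f"{path}: interval overlaps the next onset at row {row}")
    beat_times = np.concatenate((t, [t[-1] + nn[-1] / 1000.0]))
    return RRSeries(beat_times=beat_times, intervals=nn, animal_id=animal_id)


def write_rr(rr: RRSeries, path: str | Path) -> None:
    """Write beat times + intervals (``time_s,nn_ms``; one row per interval)."""
    pd.DataFrame(
        {"time_s": rr.beat_times[:-1], "nn_ms": rr.intervals}
    ).to_csv(path, index=False, float_format="%.9g")


def read_ecg(path: str | Path, sampling_rate: float | None = None) -> ECGRecord:
    """Read an ECG CSV with ``time_s,mv`` columns.

    The sampling rate is inferred from the median time step unless given.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    if "mv" not in df.columns:
        raise ParseError(f"{path}: expected 'time_s,mv' columns")
    if sampling_rate is None:
        if "time_s" not in df.columns:
            raise ParseError(f"{path}: no time_s column and no sampling_rate given")
        dt = np.median(np.diff(df["time_s"].to_numpy(dtype=float)))
        sampling_rate = 1.0 / dt
    return ECGRecord(sampling_rate=float(sampling_rate), samples=df["mv"].to_numpy(dtype=float))


def write_ecg(ecg: ECGRecord, path: str | Path) -> None:
    pd.DataFrame({"time_s": ecg.times, "mv": ecg.samples}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, dtype=str)
    required = ["animal_id", "age_group", "temperature", "state", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    entries = [
        ManifestEntry(
            animal_id=r.animal_id.strip(),
            age_group=r.age_group.strip(),
            temperature=r.temperature.strip(),
            state=r.state.strip(),
            path=r.path.strip(),
        )
        for r in df.itertuples()
    ]
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def write_hrv_table(records: Iterable, path: str | Path) -> None:
    """Write one flat CSV row per :class:`~mhrv.cohort.HRVRecord`.

    An empty collection yields a header-only file.  Values are written with
    enough digits to round-trip within 1e-6 relative.
    """
    rows = [r.to_row() for r in records]
    cols = ["animal_id", "age_group", "temperature", "state"] + METRIC_COLUMNS
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    df.to_csv(path, index=False, float_format="%.10g")


def read_hrv_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
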