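"""Orchestration: configuration, per-recording analysis, and study runs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ecg as ecg_mod
from . import io as io_mod
from .cohort import (
    METRICS,
    CohortDataset,
    HRVRecord,
    group_summary,
    lmm_contrasts,
    nn_sdnn_powerlaw,
    paired_delta,
)
from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    InsufficientDataError,
    MhrvError,
)
from .frequency import (
    SCHEMES,
    band_powers,
    estimate_psd,
    resample_evenly,
    scheme_for_temperature,
)
from .io import CohortManifest, RRSeries
from .nonlinear import NonlinearSummary, beta_slope, dfa, hurst, mse
from .timedomain import summarize_time_domain

logger = logging.getLogger("mhrv")


@dataclass
class RunConfig:
    """Analysis configuration with the package defaults.

    ``analysis_window`` optionally restricts the analysis to
    (start_s, length_s) of each recording; by default records are analysed
    whole.
    """

    resample_rate: float = 20.0  # Hz
    welch_segment_s: float = 60.0
    welch_overlap: float = 0.5
    welch_window: str = "hann"
    clean_min_ms: float = 50.0
    clean_max_ms: float = 350.0
    clean_max_rel_dev: float = 0.3
    mse_scales: int = 10
    mse_m: int = 2
    mse_r_frac: float = 0.15
    dfa_order: int = 1
    beta_fit_low: float | None = None  # default: lowest nonzero PSD bin
    beta_fit_high: float | None = None  # default: LF upper cut-off of the scheme
    analysis_window: tuple[float, float] | None = None  # (start_s, length_s)
    seed: int | None = None
    scheme_map: dict = field(default_factory=lambda: {"20C": "20C", "30C": "30C"})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "analysis_window" in raw and raw["analysis_window"] is not None:
            raw["analysis_window"] = tuple(raw["analysis_window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if data["analysis_window"] is not None:
            data["analysis_window"] = list(data["analysis_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def config_hash(self) -> str:
        data = asdict(self)
        if data["analysis_window"] is not None:
            data["analysis_window"] = list(data["analysis_window"])
        return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()[:12]

    def scheme_for(self, temperature: str):
        return scheme_for_temperature(self.scheme_map.get(temperature, temperature))


def _apply_window(rr: RRSeries, window: tuple[float, float] | None) -> RRSeries:
    if window is None:
        return rr
    start, length = window
    t0 = rr.beat_times[0] + start
    mask = (rr.beat_times[:-1] >= t0) & (rr.beat_times[:-1] < t0 + length)
    valid = rr.valid & mask
    return rr.replace(valid=valid)


def analyze_recording(
    rr: RRSeries,
    config: RunConfig,
    temperature: str,
    age_group: str = "",
    state: str = "",
) -> HRVRecord:
    """Run all three metric domains on one cleaned series.

    A domain that fails with an insufficient-data/degenerate error is left
    ``None`` and noted; the others are still computed.
    """
    scheme = config.scheme_for(temperature)
    if not rr.cleaned:
        rr = ecg_mod.clean_rr(
            rr, config.clean_min_ms, config.clean_max_ms, config.clean_max_rel_dev
        )
    rr = _apply_window(rr, config.analysis_window)
    record = HRVRecord(
        animal_id=rr.animal_id,
        age_group=age_group,
        temperature=temperature,
        state=state,
    )
    try:
        record.time = summarize_time_domain(rr)
    except (InsufficientDataError, DegenerateInputError) as exc:
        record.notes.append(f"time: {exc}")

    spec = None
    try:
        uniform = resample_evenly(rr, config.resample_rate)
        spec = estimate_psd(
            uniform,
            segment_s=config.welch_segment_s,
            overlap=config.welch_overlap,
            window=config.welch_window,
        )
        record.bands = band_powers(spec, scheme)
    except (InsufficientDataError, DegenerateInputError) as exc:
        record.notes.append(f"frequency: {exc}")

    try:
        nn = rr.nn
        if spec is None:
            raise InsufficientDataError("no spectral estimate for beta slope")
        beta = beta_slope(
            spec,
            fit_low=config.beta_fit_low,
            fit_high=config.beta_fit_high if config.beta_fit_high is not None else scheme.lf[1],
        )
        profile, mse_scalar = mse(
            nn, scales=config.mse_scales, m=config.mse_m, r_frac=config.mse_r_frac
        )
        record.nonlinear = NonlinearSummary(
            beta=beta,
            mse_profile=profile,
            mse=mse_scalar,
            dfa_alpha=dfa(nn, order=config.dfa_order),
            hurst=hurst(nn),
        )
    except (InsufficientDataError, DegenerateInputError) as exc:
        record.notes.append(f"nonlinear: {exc}")

    if record.notes:
        logger.info("%s incomplete: %s", rr.animal_id, "; ".join(record.notes))
    return record


@dataclass
class StudyResult:
    cohort: CohortDataset
    n_processed: int
    n_failed: int
    tables: dict


def run_study(
    manifest: CohortManifest,
    config: RunConfig,
    out_dir: str | Path,
    figures: bool = False,
) -> StudyResult:
    """Analyze every readable manifest recording and write the study tables.

    Outputs: per-recording metrics, per-cell group summaries, paired delta
    summaries, the NN-SDNN power-law fit, and the contrast listing.
    Unreadable recordings are skipped and logged.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    n_failed = 0
    for entry in manifest:
        try:
            rr = io_mod.read_rr(entry.path, animal_id=entry.animal_id)
            rec = analyze_recording(
                rr, config, entry.temperature, age_group=entry.age_group, state=entry.state
            )
            records.append(rec)
        except (MhrvError, OSError) as exc:
            logger.warning("skipping %s (%s): %s", entry.animal_id, entry.path, exc)
            n_failed += 1
    cohort = CohortDataset(records)
    tables: dict[str, pd.DataFrame] = {}

    io_mod.write_hrv_table(records, out_dir / "recording_metrics.csv")
    tables["recording_metrics"] = pd.read_csv(out_dir / "recording_metrics.csv")

    summaries = []
    for metric in METRICS:
        for g in group_summary(cohort, metric):
            summaries.append(
                {"metric": g.metric, "age_group": g.age_group, "temperature": g.temperature,
                 "state": g.state, "mean": g.mean, "se": g.se, "n": g.n}
            )
    tables["group_summary"] = pd.DataFrame(summaries)
    tables["group_summary"].to_csv(out_dir / "group_summary.csv", index=False)

    deltas = []
    for metric in METRICS:
        for temp in ("20C", "30C"):
            try:
                for d in paired_delta(cohort, metric, temp):
                    deltas.append(
                        {"metric": d.metric, "temperature": d.temperature,
                         "age_group": d.age_group, "mean": d.mean, "se": d.se,
                         "n_pairs": d.n_pairs}
                    )
            except MhrvError:
                pass
    tables["delta_summary"] = pd.DataFrame(deltas)
    tables["delta_summary"].to_csv(out_dir / "delta_summary.csv", index=False)

    df = cohort.to_frame().dropna(subset=["mean_nn", "sdnn"])
    df = df[df.sdnn > 0]
    if len(df) >= 3:
        slope, intercept, fit = nn_sdnn_powerlaw(df[["mean_nn", "sdnn"]].to_numpy())
        fit.insert(0, "animal_id", df.animal_id.to_numpy())
        fit.to_csv(out_dir / "nn_sdnn_powerlaw_points.csv", index=False)
        pd.DataFrame([{"slope": slope, "intercept": intercept}]).to_csv(
            out_dir / "nn_sdnn_powerlaw_fit.csv", index=False
        )
        tables["nn_sdnn_powerlaw"] = fit

    contrasts = []
    for metric in METRICS:
        try:
            c = lmm_contrasts(cohort, metric)
            c.insert(0, "metric", metric)
            contrasts.append(c)
        except MhrvError:
            pass
    if contrasts:
        tables["contrasts"] = pd.concat(contrasts, ignore_index=True)
        tables["contrasts"].to_csv(out_dir / "contrasts.csv", index=False)

    if figures:
        _write_figures(cohort, out_dir)

    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_processed": len(records),
        "n_failed": n_failed,
    }
    with open(out_dir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    logger.info("study complete: %d processed, %d failed", len(records), n_failed)
    return StudyResult(cohort=cohort, n_processed=len(records), n_failed=n_failed, tables=tables)


def _write_figures(cohort: CohortDataset, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = cohort.to_frame().dropna(subset=["mean_nn", "sdnn"])
    fig, ax = plt.subplots()
    for age, marker in (("young", "o"), ("old", "s")):
        sub = df[df.age_group == age]
        ax.loglog(sub.mean_nn, sub.sdnn, marker, label=age, alpha=0.7)
    ax.set_xlabel("mean NN (ms)")
    ax.set_ylabel("SDNN (ms)")
    ax.legend()
    fig.savefig(out_dir / "nn_sdnn_powerlaw.png", dpi=120)
    plt.close(fig)
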