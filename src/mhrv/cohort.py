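"""Cohort assembly and statistics over the 2x2x2 design: group mean (SE)
tables, paired basal-intrinsic deltas, the mean NN vs SDNN power law, and
mixed-model contrasts with Bonferroni correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .exceptions import EmptyDeltaError, InsufficientDataError, ValidationError
from .frequency import BandPowers
from .io import AGE_GROUPS, STATES, TEMPERATURES, METRIC_COLUMNS
from .nonlinear import NonlinearSummary
from .timedomain import TimeDomainSummary

logger = logging.getLogger("mhrv")

#: metric name -> flat column accessor used across tables
METRICS = [
    "mean_nn",
    "mean_hr",
    "sdnn",
    "cv",
    "sd1",
    "sd2",
    "total_power",
    "vlf",
    "lf",
    "hf",
    "beta",
    "mse",
    "dfa_alpha",
    "hurst",
]


@dataclass
class HRVRecord:
    """Per-recording bundle of the three metric domains."""

    animal_id: str
    age_group: str
    temperature: str
    state: str
    time: TimeDomainSummary | None = None
    bands: BandPowers | None = None
    nonlinear: NonlinearSummary | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return None not in (self.time, self.bands, self.nonlinear)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.animal_id, self.age_group, self.temperature, self.state)

    def metric(self, name: str) -> float:
        if name in ("mean_nn", "mean_hr", "sdnn", "cv", "sd1", "sd2", "n_beats"):
            return getattr(self.time, name) if self.time else np.nan
        if name in ("total_power", "vlf", "lf", "hf"):
            attr = "total" if name == "total_power" else name
            return getattr(self.bands, attr) if self.bands else np.nan
        if name in ("beta", "mse", "dfa_alpha", "hurst"):
            return getattr(self.nonlinear, name) if self.nonlinear else np.nan
        raise KeyError(f"unknown metric {name!r}")

    def to_row(self) -> dict:
        row = {
            "animal_id": self.animal_id,
            "age_group": self.age_group,
            "temperature": self.temperature,
            "state": self.state,
        }
        col_to_metric = {
            "n_beats": "n_beats",
            "mean_nn_ms": "mean_nn",
            "mean_hr_bpm": "mean_hr",
            "sdnn_ms": "sdnn",
            "cv_pct": "cv",
            "sd1_ms": "sd1",
            "sd2_ms": "sd2",
            "total_power_ms2": "total_power",
            "vlf_ms2": "vlf",
            "lf_ms2": "lf",
            "hf_ms2": "hf",
            "beta": "beta",
            "mse": "mse",
            "dfa_alpha": "dfa_alpha",
            "hurst": "hurst",
        }
        for col in METRIC_COLUMNS:
            row[col] = self.metric(col_to_metric[col])
        return row


@dataclass
class CohortDataset:
    """HRV records keyed by (animal, age, temperature, state)."""

    records: list[HRVRecord]

    def __post_init__(self) -> None:
        keys = [(r.animal_id, r.temperature, r.state) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (animal, temperature, state) record keys")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "animal_id": r.animal_id,
                "age_group": r.age_group,
                "temperature": r.temperature,
                "state": r.state,
            }
            for m in METRICS:
                row[m] = r.metric(m)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class GroupSummary:
    metric: str
    age_group: str
    temperature: str
    state: str
    mean: float
    se: float  # sample sd / sqrt(n); NaN for n == 1
    n: int


@dataclass
class DeltaSummary:
    metric: str
    temperature: str
    age_group: str
    per_animal_delta: np.ndarray  # basal - intrinsic, one value per paired animal
    mean: float
    se: float
    n_pairs: int


def group_summary(cohort: CohortDataset, metric: str) -> list[GroupSummary]:
    """Mean and standard error of a metric per (age, temperature, state) cell.

    Empty cells are omitted with a warning; single-record cells get a NaN SE.
    """
    df = cohort.to_frame()
    out = []
    for age, temp, state in product(AGE_GROUPS, TEMPERATURES, STATES):
        vals = df.loc[
            (df.age_group == age) & (df.temperature == temp) & (df.state == state),
            metric,
        ].dropna().to_numpy()
        if vals.size == 0:
            logger.warning("empty cell (%s, %s, %s) for metric %s", age, temp, state, metric)
            continue
        if vals.size == 1:
            logger.warning(
                "single record in cell (%s, %s, %s); SE undefined", age, temp, state
            )
            se = np.nan
        else:
            se = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
        out.append(
            GroupSummary(metric, age, temp, state, float(np.mean(vals)), se, int(vals.size))
        )
    return out


def paired_delta(cohort: CohortDataset, metric: str, temperature: str) -> list[DeltaSummary]:
    """Per-animal basal - intrinsic differences at one temperature, summarised
    per age group.  Animals lacking either state are excluded."""
    df = cohort.to_frame()
    df = df[df.temperature == temperature]
    out = []
    for age in AGE_GROUPS:
        sub = df[df.age_group == age]
        basal = sub[sub.state == "basal"].set_index("animal_id")[metric]
        intr = sub[sub.state == "intrinsic"].set_index("animal_id")[metric]
        paired = pd.concat({"basal": basal, "intrinsic": intr}, axis=1).dropna()
        if paired.empty:
            continue
        deltas = (paired["basal"] - paired["intrinsic"]).to_numpy()
        se = float(np.std(deltas, ddof=1) / np.sqrt(deltas.size)) if deltas.size > 1 else np.nan
        out.append(
            DeltaSummary(metric, temperature, age, deltas, float(np.mean(deltas)), se, int(deltas.size))
        )
    if not out:
        raise EmptyDeltaError(
            f"no complete basal/intrinsic pairs for {metric} at {temperature}"
        )
    return out


def nn_sdnn_powerlaw(points) -> tuple[float, float, pd.DataFrame]:
    """OLS fit of ln(SDNN) on ln(mean NN).

    ``points`` is an iterable of (mean_nn, sdnn) pairs; non-positive SDNN
    points are dropped with a warning.  Returns (slope, intercept, frame)
    where the frame holds the ln-ln coordinates and residuals.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be (mean_nn, sdnn) pairs")
    good = pts[:, 1] > 0
    if (~good).any():
        logger.warning("dropping %d points with non-positive SDNN", int((~good).sum()))
    pts = pts[good]
    if pts.shape[0] < 3:
        raise InsufficientDataError("power-law fit needs >= 3 points with SDNN > 0")
    ln_nn = np.log(pts[:, 0])
    ln_sd = np.log(pts[:, 1])
    slope, intercept = np.polyfit(ln_nn, ln_sd, 1)
    resid = ln_sd - (slope * ln_nn + intercept)
    frame = pd.DataFrame({"ln_mean_nn": ln_nn, "ln_sdnn": ln_sd, "residual": resid})
    return float(slope), float(intercept), frame


# ---------------------------------------------------------------------------
# mixed-model contrasts
# ---------------------------------------------------------------------------

def _cell_label(age: str, temp: str, state: str) -> str:
    return f"{age}_{temp}_{state}"


def _comparison_family(cells: list[str]) -> list[tuple[str, str, str]]:
    """The reported pairwise family: age within (temp, state), temperature
    within (age, state), and state within (age, temp)."""
    fam = []
    for temp, state in product(TEMPERATURES, STATES):
        fam.append((f"age@{temp}/{state}", _cell_label("young", temp, state),
                    _cell_label("old", temp, state)))
    for age, state in product(AGE_GROUPS, STATES):
        fam.append((f"temp@{age}/{state}", _cell_label(age, "20C", state),
                    _cell_label(age, "30C", state)))
    for age, temp in product(AGE_GROUPS, TEMPERATURES):
        fam.append((f"state@{age}/{temp}", _cell_label(age, temp, "basal"),
                    _cell_label(age, temp, "intrinsic")))
    return [(name, a, b) for name, a, b in fam if a in cells and b in cells]


def lmm_contrasts(cohort: CohortDataset, metric: str, alpha: float = 0.05) -> pd.DataFrame:
    """Fit ``metric ~ 0 + cell`` with a random intercept per animal (REML)
    and report Bonferroni-adjusted pairwise cell contrasts.

    Falls back to an ordinary fixed-effects model when animals have no
    repeated measures or the random-effect variance is singular.  The
    Bonferroni multiplier is the number of comparisons actually reported.
    """
    import statsmodels.formula.api as smf

    df = cohort.to_frame().dropna(subset=[metric]).copy()
    if df.empty:
        raise InsufficientDataError(f"no records with metric {metric}")
    for age in AGE_GROUPS:
        if df.loc[df.age_group == age, "animal_id"].nunique() < 2:
            raise InsufficientDataError(f"need >= 2 animals in age group {age}")
    df["cell"] = [
        _cell_label(a, t, s) for a, t, s in zip(df.age_group, df.temperature, df.state)
    ]
    df = df.rename(columns={metric: "value"})
    cells = sorted(df.cell.unique())
    family = _comparison_family(cells)

    if np.ptp(df["value"].to_numpy()) == 0:
        # no variation at all: every contrast is exactly zero
        rows = [
            {"comparison": name, "cell_a": a, "cell_b": b, "estimate": 0.0,
             "se": 0.0, "p_raw": 1.0, "p_bonferroni": 1.0, "significant": False}
            for name, a, b in family
        ]
        return pd.DataFrame(rows)

    repeated = df.groupby("animal_id").size().max() > 1
    result = None
    model_kind = "ols"
    if repeated:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = smf.mixedlm("value ~ 0 + C(cell)", df, groups=df["animal_id"])
                fit = mixed.fit(reml=True)
            if np.all(np.isfinite(fit.bse_fe)) and fit.cov_re.iloc[0, 0] > 1e-10:
                result = fit
                model_kind = "mixedlm"
        except Exception as exc:  # singular fits, convergence failures
            logger.warning("mixed model failed (%s); falling back to OLS", exc)
    if result is None:
        if repeated:
            logger.warning("random-intercept variance singular; using fixed-effects model")
        result = smf.ols("value ~ 0 + C(cell)", df).fit()

    k = len(family)
    exog_names = list(result.model.exog_names)
    rows = []
    for name, a, b in family:
        L = np.zeros((1, len(exog_names)))
        L[0, exog_names.index(f"C(cell)[{a}]")] = 1.0
        L[0, exog_names.index(f"C(cell)[{b}]")] = -1.0
        tt = result.t_test(L)
        est = float(np.atleast_1d(tt.effect)[0])
        se = float(np.atleast_1d(tt.sd.ravel())[0])
        p = float(np.atleast_1d(tt.pvalue)[0])
        p_adj = min(1.0, p * k)
        rows.append(
            {"comparison": name, "cell_a": a, "cell_b": b, "estimate": est,
             "se": se, "p_raw": p, "p_bonferroni": p_adj,
             "significant": bool(p_adj < alpha), "model": model_kind}
        )
    return pd.DataFrame(rows)
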