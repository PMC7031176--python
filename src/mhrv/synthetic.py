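"""Synthetic RR / ECG generation with the statistical structure the analysis
assumes: IPFM beat emission driven by band-limited oscillations plus a
1/f^beta broadband component, with presets calibrated to the eight design
cells (age x ambient temperature x autonomic state) of the study this
package models.

Preset calibration: mean NN from the published group mean heart rates,
SDNN targets from the published time-domain table, band variance fractions
from the published band-power table (cell value / cell sum), and the
broadband exponent from the published beta slopes.  Between-animal spread
is SE * sqrt(N) of the group heart rate, propagated to the NN scale.
Intrinsic-state parameters come from the corresponding intrinsic cells, so
the blockade-induced drop in variability is inherited from the calibration
table rather than modelled mechanistically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import ConfigurationError, GenerationError, ValidationError
from .frequency import BandScheme, scheme_for_temperature
from .io import ECGRecord, RRSeries

logger = logging.getLogger("mhrv")

DEFAULT_DURATION = 1800.0  # s
MODULATION_FS = 50.0  # Hz grid for modulation + IPFM integration


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the IPFM synthetic beat generator."""

    mean_nn: float  # ms
    sdnn_target: float  # ms
    band_fractions: tuple[float, float, float]  # (vlf, lf, hf), sums to 1
    spectral_exponent: float  # beta of the broadband VLF component (positive)
    hf_freq: float  # Hz
    lf_freq: float  # Hz
    temperature: str = "20C"  # selects the band scheme the fractions refer to
    duration: float = DEFAULT_DURATION  # s
    seed: int | None = None
    animal_sd: float = 0.0  # ms, between-animal SD of mean_nn

    def __post_init__(self) -> None:
        fr = np.asarray(self.band_fractions, dtype=float)
        if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"band_fractions must be >= 0 and sum to 1, got {self.band_fractions}"
            )
        if not self.mean_nn > 3.0 * self.sdnn_target:
            raise ValidationError(
                "mean_nn must exceed 3x sdnn_target to keep intervals positive "
                f"(mean_nn={self.mean_nn}, sdnn_target={self.sdnn_target})"
            )


# ---------------------------------------------------------------------------
# preset calibration table
# ---------------------------------------------------------------------------
# Per cell: group mean HR (bpm), its SE, group N, SDNN (ms), band powers
# (vlf, lf, hf in ms^2) and broadband exponent.  LT = 20C, TN = 30C.
_CELLS = {
    # (age, temperature, state)
    ("young", "20C", "basal"): dict(hr=598.0, hr_se=19.0, n=7, sdnn=5.08, cv=4.92,
                                    bands=(33.44, 27.91, 41.69), beta=2.14),
    ("young", "20C", "intrinsic"): dict(hr=539.0, hr_se=18.0, n=7, sdnn=1.72, cv=1.53,
                                        bands=(38.82, 21.19, 34.29), beta=3.26),
    ("young", "30C", "basal"): dict(hr=371.0, hr_se=12.0, n=13, sdnn=9.82, cv=5.98,
                                    bands=(152.76, 76.01, 185.95), beta=2.07),
    ("young", "30C", "intrinsic"): dict(hr=443.0, hr_se=6.0, n=13, sdnn=3.23, cv=2.39,
                                        bands=(83.99, 16.43, 71.35), beta=3.05),
    ("old", "20C", "basal"): dict(hr=622.0, hr_se=13.0, n=17, sdnn=1.78, cv=1.8,
                                  bands=(29.21, 12.39, 23.43), beta=3.28),
    ("old", "20C", "intrinsic"): dict(hr=499.0, hr_se=14.0, n=17, sdnn=0.97, cv=0.76,
                                      bands=(54.35, 23.82, 56.38), beta=3.58),
    ("old", "30C", "basal"): dict(hr=307.0, hr_se=9.0, n=13, sdnn=11.85, cv=6.06,
                                  bands=(267.9, 123.98, 292.0), beta=1.78),
    ("old", "30C", "intrinsic"): dict(hr=442.0, hr_se=17.0, n=15, sdnn=2.67, cv=1.93,
                                      bands=(91.09, 17.26, 114.25), beta=3.47),
}

# modulation carrier frequencies per temperature, placed inside the scheme's
# LF and HF bands and low enough that IPFM beat-rate sampling passes them
_CARRIERS = {"20C": dict(lf=1.0, hf=2.0), "30C": dict(lf=0.45, hf=1.0)}

_TEMP_ALIAS = {"LT": "20C", "TN": "30C"}


def _cell_spec(age: str, temperature: str, state: str) -> GeneratorSpec:
    cell = _CELLS[(age, temperature, state)]
    mean_nn = 60000.0 / cell["hr"]
    fr = np.asarray(cell["bands"], dtype=float)
    fr = fr / fr.sum()
    hr_sd = cell["hr_se"] * np.sqrt(cell["n"])
    # propagate HR spread to the NN scale: d(nn)/d(hr) = -60000 / hr^2
    animal_sd = hr_sd * 60000.0 / cell["hr"] ** 2
    carriers = _CARRIERS[temperature]
    return GeneratorSpec(
        mean_nn=mean_nn,
        sdnn_target=cell["sdnn"],
        band_fractions=tuple(fr),
        spectral_exponent=cell["beta"],
        hf_freq=carriers["hf"],
        lf_freq=carriers["lf"],
        temperature=temperature,
        animal_sd=animal_sd,
    )


def _build_presets() -> dict[str, GeneratorSpec]:
    presets = {}
    for (age, temp, state) in _CELLS:
        label = "LT" if temp == "20C" else "TN"
        presets[f"{age}_{state}_{label}"] = _cell_spec(age, temp, state)
    return presets


PRESETS: dict[str, GeneratorSpec] = _build_presets()


def preset(name: str) -> GeneratorSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def preset_cell(name: str) -> tuple[str, str, str]:
    """(age_group, temperature, state) encoded in a preset name."""
    age, state, label = name.split("_")
    return age, _TEMP_ALIAS[label], state


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def _fgn_autocov(h: float, lags: np.ndarray) -> np.ndarray:
    k = np.abs(lags.astype(float))
    return 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))


def generate_fgn(H: float, n: int, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Unit-variance fractional Gaussian noise via Davies–Harte circulant
    embedding; falls back to spectral synthesis if the embedding is not
    positive semi-definite."""
    if not 0.0 < H < 1.0:
        raise ValidationError("H must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = 2 * n
    row = np.empty(m)
    row[: n + 1] = _fgn_autocov(H, np.arange(n + 1))
    row[n + 1:] = row[1:n][::-1]
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        warnings.warn(
            "circulant embedding not positive semi-definite; "
            "falling back to spectral synthesis",
            stacklevel=2,
        )
        return _fgn_spectral(H, n, rng)
    lam = np.clip(lam, 0.0, None)
    v = np.empty(m, dtype=complex)
    u = rng.standard_normal(m)
    w = rng.standard_normal(m)
    v[0] = np.sqrt(lam[0]) * u[0]
    v[n] = np.sqrt(lam[n]) * u[n]
    k = np.arange(1, n)
    v[k] = np.sqrt(lam[k] / 2.0) * (u[k] + 1j * w[k])
    v[m - k] = np.conj(v[k])
    x = np.fft.fft(v).real[:n] / np.sqrt(m)
    return x


def _fgn_spectral(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    f = np.fft.rfftfreq(2 * n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** ((1.0 - 2.0 * H) / 2.0)
    phase = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
    x = np.fft.irfft(amp * phase, 2 * n)[:n]
    return (x - x.mean()) / x.std(ddof=0)


# ---------------------------------------------------------------------------
# modulation + IPFM
# ---------------------------------------------------------------------------

def _normalize(x: np.ndarray, target_sd: float) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) * (target_sd / sd)


def generate_modulation(
    spec: GeneratorSpec,
    fs: float = MODULATION_FS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniformly sampled NN modulation (ms deviations around the mean).

    Sum of an HF sinusoid, an LF sinusoid with slow phase drift, and
    1/f^beta Gaussian noise band-limited to the VLF band; component SDs are
    scaled so the total SD equals ``sdnn_target`` with band variance shares
    equal to ``band_fractions``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    scheme = scheme_for_temperature(spec.temperature)
    f_vlf, f_lf, f_hf = spec.band_fractions
    if f_hf > 0 and not (scheme.hf[0] <= spec.hf_freq < scheme.hf[1]):
        raise ConfigurationError(
            f"hf_freq {spec.hf_freq} Hz outside the {scheme.label} HF band {scheme.hf}"
        )
    if f_lf > 0 and not (scheme.lf[0] <= spec.lf_freq < scheme.lf[1]):
        raise ConfigurationError(
            f"lf_freq {spec.lf_freq} Hz outside the {scheme.label} LF band {scheme.lf}"
        )
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    out = np.zeros(n)
    sd = spec.sdnn_target
    if f_hf > 0:
        phi = rng.uniform(0, 2 * np.pi)
        out += _normalize(np.sin(2 * np.pi * spec.hf_freq * t + phi), np.sqrt(f_hf) * sd)
    if f_lf > 0:
        phi = rng.uniform(0, 2 * np.pi)
        drift = 0.5 * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi))
        out += _normalize(
            np.sin(2 * np.pi * spec.lf_freq * t + phi + drift), np.sqrt(f_lf) * sd
        )
    if f_vlf > 0:
        out += _normalize(
            _powerlaw_band_noise(spec.spectral_exponent, n, fs, scheme, rng),
            np.sqrt(f_vlf) * sd,
        )
    return out


#: low-frequency edge of the broadband component.  Variance below the Welch
#: segment resolution (1/60 s) would be removed by per-segment detrending and
#: never reach the analysed VLF band, so the generator does not place any there.
VLF_LOW_CUT_HZ = 1.0 / 60.0


def _powerlaw_band_noise(
    beta: float, n: int, fs: float, scheme: BandScheme, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with PSD ~ f^-beta inside the VLF band, zero elsewhere."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros(f.size)
    band = (f >= VLF_LOW_CUT_HZ) & (f <= scheme.vlf[1])
    amp[band] = f[band] ** (-beta / 2.0)
    noise = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
    return np.fft.irfft(amp * noise, n)


def ipfm_beats(
    modulation: np.ndarray,
    mean_nn: float,
    fs: float = MODULATION_FS,
    animal_id: str = "",
) -> RRSeries:
    """Integral pulse frequency modulation: a beat is emitted every time the
    running integral of the instantaneous rate 1/NN(t) crosses an integer.
    """
    nn_t = mean_nn + np.asarray(modulation, dtype=float)  # ms
    if np.any(nn_t <= 0):
        t_bad = np.argmax(nn_t <= 0) / fs
        raise GenerationError(
            f"instantaneous NN non-positive at t = {t_bad:.3f} s; "
            "reduce sdnn_target or raise mean_nn"
        )
    rate = 1000.0 / nn_t  # beats / s
    t = np.arange(nn_t.size) / fs
    integral = cumulative_trapezoid(rate, t, initial=0.0)
    n_beats = int(np.floor(integral[-1]))
    beat_times = np.interp(np.arange(n_beats + 1, dtype=float), integral, t)
    return RRSeries.from_beat_times(beat_times, animal_id=animal_id)


def simulate_rr(
    spec_or_name: GeneratorSpec | str,
    duration: float | None = None,
    seed: int | None = None,
    mean_nn_override: float | None = None,
    animal_id: str = "",
) -> RRSeries:
    """Generate one RR series from a spec or preset name (seeded)."""
    spec = preset(spec_or_name) if isinstance(spec_or_name, str) else spec_or_name
    if duration is not None:
        spec = replace(spec, duration=duration)
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    mod = generate_modulation(spec, rng=rng)
    mean_nn = mean_nn_override if mean_nn_override is not None else spec.mean_nn
    return ipfm_beats(mod, mean_nn, animal_id=animal_id)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRecording:
    animal_id: str
    age_group: str
    temperature: str
    state: str
    rr: RRSeries


def generate_cohort(
    n_per_cell: int,
    seed: int | None = None,
    duration: float = DEFAULT_DURATION,
) -> tuple[list[SimulatedRecording], "pd.DataFrame"]:
    """Simulate the 2x2x2 study design.

    Each of the eight presets contributes ``n_per_cell`` animals; every
    animal carries a single Normal(0, animal_sd) random effect on mean NN
    that is shared by its basal and intrinsic recordings at its assigned
    temperature.  Returns the recordings plus a truth table with one row per
    animal (generating parameters for both states).
    """
    import pandas as pd

    if n_per_cell < 2:
        raise ValidationError("n_per_cell must be >= 2")
    rng = np.random.default_rng(seed)
    recordings: list[SimulatedRecording] = []
    truth_rows = []
    idx = 0
    for name in sorted(PRESETS):
        age, temp, _ = preset_cell(name)
        own = preset(name)
        for _ in range(n_per_cell):
            idx += 1
            animal = f"m{idx:03d}"
            offset = rng.normal(0.0, own.animal_sd)
            row = {"animal_id": animal, "age_group": age, "temperature": temp,
                   "spawning_preset": name, "nn_offset_ms": offset}
            for state in ("basal", "intrinsic"):
                spec = _cell_spec(age, temp, state)
                spec = replace(spec, duration=duration)
                rr = simulate_rr(
                    spec,
                    seed=int(rng.integers(0, 2**63 - 1)),
                    mean_nn_override=spec.mean_nn + offset,
                    animal_id=animal,
                )
                recordings.append(
                    SimulatedRecording(animal, age, temp, state, rr)
                )
                row[f"{state}_mean_nn_ms"] = spec.mean_nn + offset
                row[f"{state}_sdnn_ms"] = spec.sdnn_target
            truth_rows.append(row)
    return recordings, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

QRS_FWHM_MS = 8.0


def synthesize_ecg(
    rr: RRSeries,
    fs: float = 1000.0,
    snr_db: float = float("inf"),
    seed: int | None = None,
) -> ECGRecord:
    """Place a Gaussian-bump QRS template (8 ms FWHM, 1 mV) at each beat
    time and add white noise at the requested SNR (signal power measured on
    the clean trace)."""
    if fs < 250:
        raise ValidationError("ECG synthesis requires fs >= 250 Hz")
    sigma = QRS_FWHM_MS / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    pad = 0.05
    n = int(round((rr.beat_times[-1] + pad) * fs)) + 1
    x = np.zeros(n)
    half = int(round(4 * sigma * fs))
    k = np.arange(-half, half + 1)
    for bt in rr.beat_times:
        center = int(round(bt * fs))
        tt = (center + k) / fs - bt
        lo, hi = center - half, center + half + 1
        klo = max(0, -lo)
        khi = k.size - max(0, hi - n)
        x[max(lo, 0):min(hi, n)] += np.exp(-(tt[klo:khi] ** 2) / (2 * sigma**2))
    if np.isfinite(snr_db):
        p_signal = np.mean(x**2)
        sigma_n = np.sqrt(p_signal / 10 ** (snr_db / 10.0))
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, sigma_n, size=n)
    return ECGRecord(sampling_rate=fs, samples=x)
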