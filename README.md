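# mhrv

Murine heart-rate / heart-rate-variability analysis toolkit:

- **Signal I/O** — RR/NN interval CSVs, single-lead ECG CSVs, cohort
  manifests for a 2 (age) × 2 (ambient temperature) × 2 (autonomic state)
  design, YAML run configuration.
- **ECG processing** — derivative-energy R-peak detection with an adaptive
  rolling median + MAD threshold and refractory enforcement; RR artifact
  cleaning (range + 9-beat running-median screen).
- **Time domain** — mean NN, mean HR (60000 / mean NN), SDNN (sample SD),
  CV, Poincaré SD1/SD2.
- **Frequency domain** — cubic-spline even resampling (20 Hz), Welch PSD
  (60-s Hann segments, 50 % overlap, linear detrend, ms²/Hz), and
  **temperature-adjusted band powers**: VLF/LF/HF cut-offs are
  0–0.5 / 0.5–1.5 / 1.5–5.0 Hz at 20 °C and 0–0.2 / 0.2–0.75 / 0.75–3.0 Hz
  at 30 °C, so band assignment tracks the beating rate.
- **Non-linear domain** — β-slope of the log–log PSD, sample entropy and
  multiscale entropy (scales 1–10, m = 2, r = 0.15·SD), DFA exponent, and a
  bias-corrected rescaled-range Hurst exponent.
- **Cohort statistics** — per-cell mean (SE) tables, paired
  Δ(basal − intrinsic) summaries, the ln(mean NN)–ln(SDNN) power law, and
  REML mixed-model cell contrasts (random animal intercept) with Bonferroni
  correction.
- **Synthetic cohort** — an IPFM (integral pulse frequency modulation) beat
  generator driven by HF/LF sinusoids plus band-limited 1/f^β noise, with
  eight presets calibrated to the published design-cell means (HR, SDNN,
  band-power fractions, spectral exponent, between-animal spread); exact
  Davies–Harte fractional Gaussian noise; Gaussian-bump ECG synthesis.

## CLI

```bash
# one synthetic recording from a calibrated preset
mhrv simulate --preset young_basal_LT --duration 1800 --seed 42 --out rr.csv

# full synthetic cohort (RR CSVs + manifest + generating truth table)
mhrv simulate-cohort --n 12 --seed 7 --out cohort/

# R-peak detection on an ECG CSV (time_s,mv)
mhrv detect --input ecg.csv --fs 1000 --refractory-ms 30 --out rr.csv

# analyze a single RR series with a band scheme
mhrv analyze --input rr.csv --scheme 30C --out metrics.csv

# full study: per-recording metrics, group/delta tables, power law, contrasts
mhrv report --manifest cohort/manifest.csv --out tables/
```

Presets: `{young,old}_{basal,intrinsic}_{LT,TN}` (LT = 20 °C, TN = 30 °C).
Analysis options (resampling rate, Welch parameters, cleaning thresholds,
non-linear settings, optional analysis window, scheme overrides) live in a
YAML config passed via `--config`; see `mhrv.pipeline.RunConfig` for keys
and defaults.

## Output table columns

`recording_metrics.csv` has one row per recording:
`animal_id, age_group, temperature, state` plus `n_beats, mean_nn_ms,
mean_hr_bpm, sdnn_ms, cv_pct, sd1_ms, sd2_ms` (time domain),
`total_power_ms2, vlf_ms2, lf_ms2, hf_ms2` (frequency domain) and
`beta, mse, dfa_alpha, hurst` (non-linear domain). `group_summary.csv` /
`delta_summary.csv` aggregate these per design cell and per paired
basal − intrinsic comparison (mean, SE, n).

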