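import numpy as np
import pytest

from mhrv.ecg import clean_rr
from mhrv.exceptions import ConfigurationError, GenerationError, ValidationError
from mhrv.frequency import SCHEME_30C, band_powers, estimate_psd, resample_evenly
from mhrv.nonlinear import beta_slope
from mhrv.synthetic import (
    PRESETS,
    GeneratorSpec,
    generate_cohort,
    generate_fgn,
    generate_modulation,
    ipfm_beats,
    preset,
    preset_cell,
    simulate_rr,
    synthesize_ecg,
)
from mhrv.timedomain import summarize_time_domain


class TestFGN:
    def test_white_case_uncorrelated(self):
        x = generate_fgn(0.5, 8192, seed=0)
        rho1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(rho1) < 0.05

    def test_lag1_autocorrelation_h08(self):
        rhos = [
            np.corrcoef(generate_fgn(0.8, 8192, seed=s)[:-1], generate_fgn(0.8, 8192, seed=s)[1:])[0, 1]
            for s in range(5)
        ]
        theory = 2 ** (2 * 0.8 - 1) - 1  # ~0.5157
        assert np.mean(rhos) == pytest.approx(theory, abs=0.05)

    def test_deterministic(self):
        np.testing.assert_array_equal(generate_fgn(0.7, 512, seed=42), generate_fgn(0.7, 512, seed=42))

    def test_unit_variance(self):
        x = generate_fgn(0.6, 16384, seed=1)
        assert np.var(x) == pytest.approx(1.0, rel=0.1)

    def test_h_out_of_range(self):
        with pytest.raises(ValidationError):
            generate_fgn(1.2, 256, seed=0)


class TestGeneratorSpec:
    def test_fraction_validation(self):
        with pytest.raises(ValidationError):
            GeneratorSpec(
                mean_nn=100.0, sdnn_target=5.0, band_fractions=(0.5, 0.2, 0.2),
                spectral_exponent=2.0, hf_freq=2.0, lf_freq=1.0,
            )

    def test_positivity_guard(self):
        with pytest.raises(ValidationError):
            GeneratorSpec(
                mean_nn=100.0, sdnn_target=40.0, band_fractions=(0.4, 0.3, 0.3),
                spectral_exponent=2.0, hf_freq=2.0, lf_freq=1.0,
            )

    def test_presets_registry(self):
        assert len(PRESETS) == 8
        spec = preset("young_basal_LT")
        assert spec.mean_nn == pytest.approx(60000.0 / 598.0)
        assert spec.sdnn_target == 5.08
        assert preset_cell("old_intrinsic_TN") == ("old", "30C", "intrinsic")
        assert preset("old_basal_TN").band_fractions == pytest.approx(
            (267.9 / 683.88, 123.98 / 683.88, 292.0 / 683.88), abs=1e-9
        )

    def test_unknown_preset(self):
        with pytest.raises(ConfigurationError):
            preset("middle_basal_LT")


class TestModulation:
    def test_pure_hf_sd_and_concentration(self):
        spec = GeneratorSpec(
            mean_nn=100.0, sdnn_target=5.0, band_fractions=(0.0, 0.0, 1.0),
            spectral_exponent=2.0, hf_freq=2.0, lf_freq=1.0, temperature="20C",
            duration=300.0,
        )
        mod = generate_modulation(spec, rng=np.random.default_rng(0))
        assert np.std(mod) == pytest.approx(5.0, rel=0.01)
        freqs = np.fft.rfftfreq(mod.size, d=1 / 50.0)
        power = np.abs(np.fft.rfft(mod)) ** 2
        assert freqs[np.argmax(power)] == pytest.approx(2.0, abs=0.02)

    def test_hf_freq_outside_band_rejected(self):
        spec = GeneratorSpec(
            mean_nn=100.0, sdnn_target=5.0, band_fractions=(0.0, 0.0, 1.0),
            spectral_exponent=2.0, hf_freq=1.0, lf_freq=1.0, temperature="20C",
        )
        with pytest.raises(ConfigurationError):
            generate_modulation(spec, rng=np.random.default_rng(0))

    def test_pure_vlf_beta_recovered_by_pipeline(self):
        spec = GeneratorSpec(
            mean_nn=100.0, sdnn_target=5.0, band_fractions=(1.0, 0.0, 0.0),
            spectral_exponent=2.0, hf_freq=2.0, lf_freq=1.0, temperature="20C",
            duration=1800.0,
        )
        betas = []
        for s in range(3):
            rr = clean_rr(simulate_rr(spec, seed=s))
            est = estimate_psd(resample_evenly(rr))
            betas.append(beta_slope(est, fit_high=0.5))
        assert np.mean(betas) == pytest.approx(-2.0, abs=0.3)

    def test_old_basal_tn_band_shares_recovered(self):
        rr = clean_rr(simulate_rr("old_basal_TN", duration=1800.0, seed=1))
        bp = band_powers(estimate_psd(resample_evenly(rr)), SCHEME_30C)
        shares = np.array([bp.vlf, bp.lf, bp.hf]) / bp.total
        np.testing.assert_allclose(shares, preset("old_basal_TN").band_fractions, rtol=0.10)


class TestIPFM:
    def test_constant_rate(self):
        rr = ipfm_beats(np.zeros(60 * 50), mean_nn=100.0, fs=50.0)
        assert abs(rr.intervals.size - 600) <= 1
        np.testing.assert_allclose(rr.intervals, 100.0, atol=0.1)

    def test_sinusoid_modulation_peak(self):
        fs = 50.0
        t = np.arange(0, 300.0, 1 / fs)
        rr = ipfm_beats(5.0 * np.sin(2 * np.pi * 1.0 * t), mean_nn=100.0, fs=fs)
        spec = estimate_psd(resample_evenly(rr))
        mask = spec.frequencies > 0.1
        peak_f = spec.frequencies[mask][np.argmax(spec.psd[mask])]
        assert peak_f == pytest.approx(1.0, abs=2 * spec.df)

    def test_nonpositive_nn_rejected(self):
        mod = np.zeros(500)
        mod[250] = -150.0
        with pytest.raises(GenerationError, match="t = "):
            ipfm_beats(mod, mean_nn=100.0, fs=50.0)

    def test_preset_mean_hr(self):
        rr = clean_rr(simulate_rr("young_basal_LT", duration=600.0, seed=0))
        s = summarize_time_domain(rr)
        assert s.mean_hr == pytest.approx(598.0, rel=0.02)

    def test_sdnn_tracks_modulation_sd(self):
        spec = GeneratorSpec(
            mean_nn=150.0, sdnn_target=8.0, band_fractions=(0.4, 0.3, 0.3),
            spectral_exponent=2.0, hf_freq=1.0, lf_freq=0.45, temperature="30C",
            duration=600.0,
        )
        rr = simulate_rr(spec, seed=2)
        assert np.std(rr.intervals, ddof=1) == pytest.approx(8.0, rel=0.10)


class TestCohortGeneration:
    def test_counts_and_determinism(self):
        recs_a, truth_a = generate_cohort(2, seed=9, duration=120.0)
        recs_b, truth_b = generate_cohort(2, seed=9, duration=120.0)
        assert len({r.animal_id for r in recs_a}) == 16
        assert len(recs_a) == 32
        assert truth_a.shape[0] == 16
        for ra, rb in zip(recs_a, recs_b):
            np.testing.assert_array_equal(ra.rr.intervals, rb.rr.intervals)
        assert truth_a.equals(truth_b)

    def test_animal_effect_shared_between_states(self):
        recs, truth = generate_cohort(2, seed=3, duration=120.0)
        by_animal = {}
        for r in recs:
            by_animal.setdefault(r.animal_id, []).append(r)
        for animal, rr_list in by_animal.items():
            assert {r.state for r in rr_list} == {"basal", "intrinsic"}
            assert len({r.temperature for r in rr_list}) == 1

    def test_min_n(self):
        with pytest.raises(ValidationError):
            generate_cohort(1, seed=0)


class TestSynthesizeECG:
    def test_noise_free_maxima_at_beats(self):
        rr = ipfm_beats(np.zeros(25), mean_nn=100.0, fs=25.0)  # short train
        rr = rr.replace()  # no-op copy
        beats = rr.beat_times[:10]
        from mhrv.io import RRSeries

        rr10 = RRSeries.from_beat_times(beats)
        ecg = synthesize_ecg(rr10, fs=1000.0)
        for bt in beats:
            idx = int(round(bt * 1000.0))
            lo, hi = max(0, idx - 10), idx + 11
            local = np.argmax(ecg.samples[lo:hi]) + lo
            assert abs(local - bt * 1000.0) <= 1.0

    def test_low_fs_rejected(self, constant_rr):
        with pytest.raises(ValidationError):
            synthesize_ecg(constant_rr, fs=100.0)

    def test_snr_noise_power(self, rng):
        from mhrv.io import RRSeries

        rr = RRSeries.from_intervals(np.full(100, 100.0))
        clean = synthesize_ecg(rr, fs=1000.0)
        noisy = synthesize_ecg(rr, fs=1000.0, snr_db=10.0, seed=0)
        p_sig = np.mean(clean.samples**2)
        p_noise = np.mean((noisy.samples - clean.samples) ** 2)
        assert 10 * np.log10(p_sig / p_noise) == pytest.approx(10.0, abs=0.5)
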