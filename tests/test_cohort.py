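import numpy as np
import pytest
from scipy import stats

from mhrv.cohort import (
    CohortDataset,
    HRVRecord,
    group_summary,
    lmm_contrasts,
    nn_sdnn_powerlaw,
    paired_delta,
)
from mhrv.ecg import clean_rr
from mhrv.exceptions import EmptyDeltaError, InsufficientDataError
from mhrv.synthetic import generate_cohort
from mhrv.timedomain import TimeDomainSummary, summarize_time_domain


def _td(mean_hr, sdnn=5.0):
    mean_nn = 60000.0 / mean_hr
    return TimeDomainSummary(
        mean_nn=mean_nn, mean_hr=mean_hr, sdnn=sdnn, cv=100 * sdnn / mean_nn,
        sd1=1.0, sd2=2.0, n_beats=1000,
    )


def _rec(animal, age, temp, state, hr, sdnn=5.0):
    return HRVRecord(animal, age, temp, state, time=_td(hr, sdnn))


@pytest.fixture(scope="module")
def analyzed_cohort():
    """Time-domain-analyzed synthetic cohort at n_per_cell=12 (short records)."""
    recordings, _ = generate_cohort(12, seed=11, duration=180.0)
    records = []
    for r in recordings:
        rr = clean_rr(r.rr)
        records.append(
            HRVRecord(r.animal_id, r.age_group, r.temperature, r.state,
                      time=summarize_time_domain(rr))
        )
    return CohortDataset(records)


class TestGroupSummary:
    def test_two_values(self):
        c = CohortDataset([
            _rec("a", "young", "20C", "basal", 10.0),
            _rec("b", "young", "20C", "basal", 14.0),
        ])
        gs = group_summary(c, "mean_hr")
        assert len(gs) == 1
        assert gs[0].mean == 12.0
        assert gs[0].se == pytest.approx(2.0)
        assert gs[0].n == 2

    def test_single_record_cell_nan_se(self):
        c = CohortDataset([_rec("a", "young", "20C", "basal", 600.0)])
        gs = group_summary(c, "mean_hr")
        assert np.isnan(gs[0].se)

    def test_synthetic_cohort_cell_mean(self, analyzed_cohort):
        gs = {(g.age_group, g.temperature, g.state): g for g in group_summary(analyzed_cohort, "mean_hr")}
        g = gs[("young", "20C", "basal")]
        # recovered cell mean within 3 SE of the calibrated 598 bpm
        assert g.n >= 24
        assert abs(g.mean - 598.0) <= 3.0 * g.se


class TestPairedDelta:
    def test_arithmetic(self):
        c = CohortDataset([
            _rec("A", "young", "20C", "basal", 600.0),
            _rec("A", "young", "20C", "intrinsic", 500.0),
            _rec("B", "young", "20C", "basal", 620.0),
            _rec("B", "young", "20C", "intrinsic", 540.0),
        ])
        (d,) = paired_delta(c, "mean_hr", "20C")
        np.testing.assert_allclose(sorted(d.per_animal_delta), [80.0, 100.0])
        assert d.mean == 90.0
        assert d.se == pytest.approx(10.0)
        assert d.n_pairs == 2

    def test_unpaired_animal_excluded(self):
        c = CohortDataset([
            _rec("A", "young", "20C", "basal", 600.0),
            _rec("A", "young", "20C", "intrinsic", 500.0),
            _rec("B", "young", "20C", "basal", 620.0),
        ])
        (d,) = paired_delta(c, "mean_hr", "20C")
        assert d.n_pairs == 1

    def test_sign_convention_tn(self, analyzed_cohort):
        # at thermoneutrality HR rises after blockade -> basal - intrinsic < 0
        deltas = paired_delta(analyzed_cohort, "mean_hr", "30C")
        for d in deltas:
            assert d.mean < 0

    def test_empty_raises(self):
        c = CohortDataset([_rec("A", "young", "20C", "basal", 600.0)])
        with pytest.raises(EmptyDeltaError):
            paired_delta(c, "mean_hr", "30C")

    def test_delta_equals_group_mean_difference_when_balanced(self, analyzed_cohort):
        gs = {(g.age_group, g.temperature, g.state): g for g in group_summary(analyzed_cohort, "mean_hr")}
        for d in paired_delta(analyzed_cohort, "mean_hr", "20C"):
            expected = gs[(d.age_group, "20C", "basal")].mean - gs[(d.age_group, "20C", "intrinsic")].mean
            assert d.mean == pytest.approx(expected, abs=1e-9)


class TestPowerlaw:
    def test_exact_quadratic(self):
        nn = np.linspace(80.0, 200.0, 20)
        slope, intercept, frame = nn_sdnn_powerlaw(np.column_stack((nn, 0.001 * nn**2)))
        assert slope == pytest.approx(2.0, abs=1e-9)
        assert intercept == pytest.approx(np.log(0.001), abs=1e-9)
        assert np.allclose(frame.residual, 0.0, atol=1e-12)

    def test_two_point_slope_plus_anchor(self):
        pts = [(100.0, 2.0), (200.0, 8.0), (400.0, 32.0)]  # exact slope 2
        slope, _, _ = nn_sdnn_powerlaw(pts)
        assert slope == pytest.approx(np.log(4.0) / np.log(2.0), abs=1e-9)

    def test_nonpositive_dropped(self):
        pts = [(100.0, 2.0), (200.0, 8.0), (400.0, 32.0), (150.0, 0.0)]
        slope, _, frame = nn_sdnn_powerlaw(pts)
        assert len(frame) == 3
        assert slope == pytest.approx(2.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            nn_sdnn_powerlaw([(100.0, 2.0), (200.0, 8.0)])

    def test_synthetic_cohort_positive_slope(self, analyzed_cohort):
        df = analyzed_cohort.to_frame()
        slope, _, _ = nn_sdnn_powerlaw(df[["mean_nn", "sdnn"]].to_numpy())
        assert slope > 0  # SDNN grows with mean NN


class TestLMM:
    def test_degenerates_to_t_test(self):
        rng = np.random.default_rng(4)
        ya = rng.normal(600.0, 20.0, 8)
        ob = rng.normal(570.0, 20.0, 8)
        recs = [_rec(f"y{i}", "young", "20C", "basal", v) for i, v in enumerate(ya)]
        recs += [_rec(f"o{i}", "old", "20C", "basal", v) for i, v in enumerate(ob)]
        out = lmm_contrasts(CohortDataset(recs), "mean_hr")
        row = out[out.comparison == "age@20C/basal"].iloc[0]
        _, p_ref = stats.ttest_ind(ya, ob)
        assert row.model == "ols"
        assert row.p_raw == pytest.approx(p_ref, abs=1e-6)
        assert row.estimate == pytest.approx(ya.mean() - ob.mean(), abs=1e-9)

    def test_identical_metric(self):
        recs = [_rec(f"y{i}", "young", "20C", "basal", 600.0) for i in range(3)]
        recs += [_rec(f"o{i}", "old", "20C", "basal", 600.0) for i in range(3)]
        out = lmm_contrasts(CohortDataset(recs), "mean_hr")
        assert (out.estimate == 0.0).all()
        assert (out.p_bonferroni == 1.0).all()

    def test_bonferroni_bounds(self, analyzed_cohort):
        out = lmm_contrasts(analyzed_cohort, "mean_hr")
        assert (out.p_bonferroni >= out.p_raw - 1e-15).all()
        assert (out.p_bonferroni <= 1.0).all()

    def test_age_gap_at_tn_detected(self, analyzed_cohort):
        out = lmm_contrasts(analyzed_cohort, "mean_hr")
        row = out[out.comparison == "age@30C/basal"].iloc[0]
        assert row.significant  # generator imposes 371 vs 307 bpm at TN
        assert row.estimate > 0

    def test_too_few_animals(self):
        recs = [_rec("a", "young", "20C", "basal", 600.0), _rec("b", "old", "20C", "basal", 590.0)]
        with pytest.raises(InsufficientDataError):
            lmm_contrasts(CohortDataset(recs), "mean_hr")
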