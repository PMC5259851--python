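"""Kaplan-Meier / weighted Kaplan-Meier curves and the nonparametric AR."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter

import arsurv as av


def _sample(time, event, exposure=None):
    time = np.asarray(time, float)
    exposure = np.zeros_like(time, dtype=int) if exposure is None else np.asarray(exposure)
    return av.CohortSample(time, np.asarray(event), exposure)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        curve = av.km_survival(_sample([1, 2, 3], [1, 1, 1]))
        assert curve(1.5) == pytest.approx(2 / 3)
        assert curve(3.0) == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set(self):
        # times {1+, 2, 3}: at t=2 the risk set has 2 subjects
        curve = av.km_survival(_sample([1, 2, 3], [0, 1, 1]))
        assert curve(2.0) == pytest.approx(0.5)

    def test_single_subject_step(self):
        curve = av.km_survival(_sample([5.0], [1]))
        assert curve(4.999) == 1.0
        assert curve(5.0) == 0.0

    def test_hand_computed_toy_values(self, toy_sample):
        curve = av.km_survival(toy_sample, restrict_stratum=0)
        for t, expected in [(1.0, 4 / 5), (3.0, 8 / 15), (4.0, 4 / 15)]:
            assert curve(t) == pytest.approx(expected)

    def test_empty_stratum_raises_named_error(self, toy_sample):
        with pytest.raises(av.EmptyStratumError, match="7"):
            av.km_survival(toy_sample, restrict_stratum=7)

    def test_matches_lifelines_on_censored_data(self, ph_sample):
        ours = av.km_survival(ph_sample)
        kmf = KaplanMeierFitter().fit(ph_sample.time, ph_sample.event)
        grid = np.linspace(0.5, 19.5, 39)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        assert np.allclose(ours(grid), theirs, atol=1e-12)

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=100, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_equals_empirical_survival_without_censoring(self, times):
        times = np.asarray(times)
        curve = av.km_survival(_sample(times, np.ones(times.size, int)))
        grid = np.unique(times)
        empirical = 1.0 - np.searchsorted(np.sort(times), grid, side="right") / times.size
        assert np.allclose(curve(grid), empirical, atol=1e-12)


class TestWeightedKaplanMeier:
    def test_single_stratum_collapses_to_km(self, ph_sample):
        pooled = av.CohortSample(
            ph_sample.time,
            ph_sample.event,
            ph_sample.exposure,
            np.zeros(ph_sample.n, int),
        )
        km = av.km_survival(pooled)
        wkm = av.wkm_survival(pooled)
        grid = np.linspace(0.1, 20, 50)
        assert np.allclose(wkm(grid), km(grid), atol=1e-12)

    def test_stratum_size_weighting(self):
        # strata sizes 4 and 1 with per-stratum KM 0.75 and 0.0 at t=2
        sample = av.CohortSample(
            np.array([1.0, 3, 3, 3, 1.0]),
            np.array([1, 0, 0, 0, 1]),
            np.array([0, 0, 0, 0, 1]),
        )
        # stratum 0: n=4, one event among 4 -> S=0.75; stratum 1: n=1, event -> S=0
        wkm = av.wkm_survival(sample)
        assert wkm(2.0) == pytest.approx((4 * 0.75 + 1 * 0.0) / 5)

    def test_equal_weights_average(self):
        sample = av.CohortSample(
            np.array([1.0, 5, 2, 5]),
            np.array([1, 0, 1, 0]),
            np.array([0, 0, 1, 1]),
        )
        # each stratum: S=1/2 after its event
        assert av.wkm_survival(sample)(3.0) == pytest.approx(0.5)


class TestNonparametricAR:
    def test_zero_when_exposure_has_no_effect(self):
        # identical event patterns in both groups -> pooled and baseline curves agree
        time = np.array([1.0, 2, 3, 4, 1.0, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        exposure = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        curve = av.ar_nonparametric(
            av.CohortSample(time, event, exposure), [2.5], variance_method="none"
        )
        assert curve.estimate[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_survival_ratio(self):
        # with S0=0.7937 and S=0.71184 the AR formula gives 0.284
        ar = 1 - (1 - 0.7937) / (1 - 0.71184)
        assert ar == pytest.approx(0.284, abs=5e-4)

    def test_undefined_before_first_event_reported_missing(self, toy_sample):
        curve = av.ar_nonparametric(
            toy_sample, [0.5, 3.0], variance_method="none"
        )
        assert np.isnan(curve.estimate[0])
        assert np.isfinite(curve.estimate[1])

    def test_no_unexposed_subjects_is_an_error(self):
        sample = _sample([1, 2, 3], [1, 1, 1], [1, 1, 1])
        with pytest.raises(av.EmptyStratumError):
            av.ar_nonparametric(sample, [2.0], variance_method="none")

    def test_exposure_relabel_leaves_pooled_survival_unchanged(self, ph_sample):
        flipped = av.CohortSample(
            ph_sample.time, ph_sample.event, 1 - ph_sample.exposure
        )
        grid = np.linspace(0.5, 19.5, 20)
        assert np.allclose(
            av.km_survival(ph_sample)(grid), av.km_survival(flipped)(grid)
        )

    def test_estimate_never_exceeds_one_and_bootstrap_se_positive(self, ph_sample):
        curve = av.ar_nonparametric(
            ph_sample, [5.0, 10.0], boot_reps=50, seed=1
        )
        assert np.all(curve.estimate <= 1.0)
        assert np.all(curve.se > 0)
        assert np.all(curve.ci_low <= curve.estimate)
        assert np.all(curve.estimate <= curve.ci_high)

    @pytest.mark.parametrize("weighting", ["KM", "WKM"])
    def test_consistency_under_proportional_hazards(self, weighting):
        config = av.ScenarioConfig(model="PH", n=40000, seed=9)
        sample = av.generate_ph(config, av.replicate_rng(9, 0))
        curve = av.ar_nonparametric(
            sample, [5.0, 15.0], weighting=weighting, variance_method="none"
        )
        truth = av.theoretical_ar(config, [5.0, 15.0])
        # 3x the n=10,000 sampling SD scaled to n=40,000
        tol = 3 * np.array([0.0166, 0.0114]) / 2
        assert np.all(np.abs(curve.estimate - truth) < tol)
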