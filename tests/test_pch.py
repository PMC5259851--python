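"""Piecewise-constant-hazards fit, interval exposure times and parametric AR."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

import arsurv as av

CUTS = (5.0, 10.0, 15.0, 20.0)


class TestExposureTime:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (7.0, [5, 2, 0, 0]),
            (0.0, [0, 0, 0, 0]),
            (20.0, [5, 5, 5, 5]),
            (5.0, [5, 0, 0, 0]),
            (19.0, [5, 5, 5, 4]),
        ],
    )
    def test_three_case_definition(self, t, expected):
        assert np.allclose(av.exposure_time(t, CUTS), expected)

    @given(st.floats(min_value=0.0, max_value=40.0))
    def test_components_sum_to_min_t_aJ(self, t):
        delta = av.exposure_time(t, CUTS)
        assert delta.sum() == pytest.approx(min(t, 20.0), abs=1e-9)
        assert np.all(delta >= 0)


class TestFitPCH:
    def test_single_interval_pooled_rate_is_events_over_person_time(self, ph_sample):
        fit = av.fit_pch(ph_sample, cutpoints=[20.0], fit_exposure=False)
        rate = ph_sample.event.sum() / ph_sample.time.sum()
        assert math.exp(fit.alpha[0]) == pytest.approx(rate, rel=1e-12)
        assert fit.beta == 0.0

    def test_single_interval_binary_exposure_closed_form(self, ph_sample):
        fit = av.fit_pch(ph_sample, cutpoints=[20.0])
        z = ph_sample.exposure
        rate0 = ph_sample.event[z == 0].sum() / ph_sample.time[z == 0].sum()
        rate1 = ph_sample.event[z == 1].sum() / ph_sample.time[z == 1].sum()
        assert math.exp(fit.alpha[0]) == pytest.approx(rate0, rel=1e-10)
        assert math.exp(fit.alpha[0] + fit.beta) == pytest.approx(rate1, rel=1e-10)

    def test_matches_poisson_glm_on_expanded_data(self, ph_sample):
        fit = av.fit_pch(ph_sample, cutpoints=CUTS)
        # interval-expanded Poisson log-linear model with person-time offset
        delta = av.exposure_time(ph_sample.time, CUTS)
        a = np.asarray(CUTS)
        interval = np.clip(np.searchsorted(a, ph_sample.time, side="left"), 0, 3)
        rows, cols, y, off = [], [], [], []
        for j in range(4):
            mask = delta[:, j] > 0
            x = np.zeros((mask.sum(), 5))
            x[:, j] = 1.0
            x[:, 4] = ph_sample.exposure[mask]
            rows.append(x)
            y.append((ph_sample.event[mask] == 1) & (interval[mask] == j))
            off.append(np.log(delta[mask, j]))
        X = np.vstack(rows)
        glm = sm.GLM(
            np.concatenate(y).astype(float),
            X,
            family=sm.families.Poisson(),
            offset=np.concatenate(off),
        ).fit()
        assert np.allclose(fit.alpha, glm.params[:4], atol=1e-8)
        assert fit.beta == pytest.approx(glm.params[4], abs=1e-8)
        assert np.allclose(
            np.sqrt(np.diag(fit.cov)), glm.bse, rtol=1e-6
        )

    def test_recovers_constant_hazard_and_beta(self):
        config = av.ScenarioConfig(model="PH", n=10000, seed=21)
        sample = av.generate_ph(config, av.replicate_rng(21, 0))
        fit = av.fit_pch(sample, cutpoints=CUTS)
        true_alpha = math.log(math.log(2) / 15)  # constant hazard ln2/15
        se_alpha = np.sqrt(np.diag(fit.cov))[:4]
        assert np.all(np.abs(fit.alpha - true_alpha) < 3 * se_alpha)
        se_beta = math.sqrt(fit.cov[4, 4])
        assert fit.beta == pytest.approx(math.log(2), abs=3 * se_beta)

    def test_empty_interval_raises(self):
        sample = av.CohortSample(
            np.array([1.0, 2.0, 18.0]), np.array([1, 1, 1]), np.array([0, 1, 0])
        )
        with pytest.raises(av.EmptyIntervalError, match=r"\(5, 10\]"):
            av.fit_pch(sample, cutpoints=CUTS)

    def test_times_beyond_grid_rejected(self, ph_sample):
        with pytest.raises(ValueError, match="cutpoint"):
            av.fit_pch(ph_sample, cutpoints=[5.0, 10.0])


class TestArPCH:
    def test_zero_when_no_exposure_effect(self, ph_sample):
        # identical duplicated cohorts labelled 0/1 force beta-hat to 0
        doubled = av.CohortSample(
            np.tile(ph_sample.time, 2),
            np.tile(ph_sample.event, 2),
            np.repeat([0, 1], ph_sample.n),
        )
        curve = av.ar_pch(doubled, [5.0, 15.0], cutpoints=CUTS, variance_method="none")
        assert np.allclose(curve.estimate, 0.0, atol=1e-8)

    def test_no_extrapolation_beyond_last_cutpoint(self, ph_sample):
        with pytest.raises(ValueError, match="cutpoint"):
            av.ar_pch(ph_sample, [25.0], cutpoints=CUTS)

    def test_survival_curve_continuous_and_decreasing(self, ph_sample):
        fit = av.fit_pch(ph_sample, cutpoints=CUTS)
        grid = np.linspace(0.01, 20.0, 500)
        s = fit.survival(grid, z=0)
        assert np.all(np.diff(s) < 0)
        assert np.max(np.abs(np.diff(s))) < 0.01  # no jumps

    def test_delta_method_agrees_with_bootstrap(self, ph_sample):
        times = [5.0, 10.0, 15.0, 20.0]
        delta = av.ar_pch(ph_sample, times, cutpoints=CUTS, variance_method="delta")
        boot = av.ar_pch(
            ph_sample, times, cutpoints=CUTS, variance_method="bootstrap",
            boot_reps=500, seed=77,
        )
        assert np.all(np.abs(delta.se / boot.se - 1.0) < 0.15)

    def test_consistency_and_cutpoint_refinement(self):
        # gamma != 1: a 4-interval PCH misspecifies the Weibull baseline; a
        # 16-interval grid must move A-hat(t) closer to the closed form
        config = av.ScenarioConfig(model="PH", gamma=4 / 3, n=40000, seed=31)
        sample = av.generate_ph(config, av.replicate_rng(31, 0))
        truth = np.atleast_1d(av.theoretical_ar(config, [5.0, 20.0]))
        coarse = av.ar_pch(sample, [5.0, 20.0], cutpoints=CUTS, variance_method="none")
        fine = av.ar_pch(
            sample, [5.0, 20.0], cutpoints=np.arange(1.25, 20.1, 1.25),
            variance_method="none",
        )
        err_coarse = np.abs(coarse.estimate - truth)
        err_fine = np.abs(fine.estimate - truth)
        assert err_fine.sum() <= err_coarse.sum() + 0.002
        assert np.all(err_fine < 3 * np.array([0.0132, 0.0081]) / 2)
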