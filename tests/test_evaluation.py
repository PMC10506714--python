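"""Tests of the model-assessment suite: chi-square check, DIC, CV, discrepancies."""

import numpy as np
import pytest
from scipy import stats as sps

import streamtemp as st
from streamtemp.evaluation import conditional_moments


class TestChi2Discrepancy:
    def test_single_day_arithmetic(self):
        obs = np.array([10.0])
        E = np.array([[8.0]])
        V = np.array([[4.0]])
        chi_obs, _, _ = st.chi2_discrepancy(obs, E, V, rng=0)
        assert chi_obs[0] == pytest.approx(1.0)

    def test_perfect_fit_gives_pvalue_near_one(self):
        obs = np.linspace(5, 15, 40)
        E = np.tile(obs, (200, 1))
        V = np.ones_like(E)
        chi_obs, chi_rep, p = st.chi2_discrepancy(obs, E, V, rng=1)
        assert np.all(chi_obs == 0)
        assert p == 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            st.chi2_discrepancy(np.array([1.0]), np.array([[1.0]]),
                                np.array([[0.0]]))

    def test_correct_conditional_law_gives_calibrated_pvalues(self):
        """Data drawn from the conditional law itself yield p-values that are
        roughly uniform: central on average, neither stuck at 0 nor 1."""
        rng = np.random.default_rng(2)
        E0 = rng.normal(10, 2, size=300)
        E = np.tile(E0, (400, 1))
        V = np.full_like(E, 0.25)
        ps = []
        for k in range(30):
            obs = E0 + 0.5 * rng.standard_normal(300)
            _, _, p = st.chi2_discrepancy(obs, E, V, rng=rng)
            ps.append(p)
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) < 0.5 < max(ps)


class TestDic:
    def test_identity_and_constant_deviance(self):
        devs = np.full(50, 123.4)
        dbar, p_d, dic_val = st.dic(devs, 123.4)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        assert dic_val == pytest.approx(dbar + p_d)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            st.dic(np.array([1.0]), 1.0)

    def test_conjugate_normal_toy_has_one_effective_parameter(self):
        """iid Normal(mu, 1) with a flat-ish prior: pD is about 1."""
        rng = np.random.default_rng(5)
        n = 50
        x = rng.normal(2.0, 1.0, n)
        prior_var = 100.0
        post_var = 1.0 / (n + 1.0 / prior_var)
        post_mean = post_var * x.sum()
        mus = rng.normal(post_mean, np.sqrt(post_var), 40_000)
        devs = np.array([-2 * sps.norm.logpdf(x, m, 1.0).sum() for m in mus])
        dev_at_mean = -2 * sps.norm.logpdf(x, mus.mean(), 1.0).sum()
        _, p_d, _ = st.dic(devs, dev_at_mean)
        assert p_d == pytest.approx(1.0, abs=0.1)

    def test_half_variance_estimator_agrees_on_toy(self):
        rng = np.random.default_rng(6)
        n = 50
        x = rng.normal(0.0, 1.0, n)
        post_var = 1.0 / (n + 0.01)
        mus = rng.normal(x.mean() * n * post_var, np.sqrt(post_var), 40_000)
        devs = np.array([-2 * sps.norm.logpdf(x, m, 1.0).sum() for m in mus])
        _, p_d, _ = st.dic(devs, -2 * sps.norm.logpdf(x, mus.mean(), 1.0).sum(),
                           pd_variant="half_var")
        assert p_d == pytest.approx(1.0, abs=0.15)


class TestFitDiagnostics:
    def test_dic_identity_on_fit(self, small_fit):
        draws, _, _ = small_fit
        dbar, p_d, dic_val = st.dic_from_fit(draws, n_draws=300)
        assert dic_val == pytest.approx(dbar + p_d, abs=1e-9)
        assert p_d > 0  # a fitted hierarchical model has positive complexity

    def test_posterior_check_is_central_for_generating_model(self, small_fit):
        draws, _, _ = small_fit
        p = st.posterior_check(draws, n_draws=400, seed=0)
        assert 0.2 <= p <= 0.8

    def test_diagnostics_row_shape(self, small_fit):
        draws, _, _ = small_fit
        diag = st.evaluate_fit(draws, rmse=1.23, n_draws=300, seed=0)
        row = diag.row("M2")
        assert set(row) == {"model", "RMSE", "chi2_pvalue", "deviance", "pD", "DIC"}
        assert row["RMSE"] == 1.23

    def test_moment_shapes(self, small_fit, small_data):
        draws, _, _ = small_fit
        data, _ = small_data
        E, V, idx = conditional_moments(draws, n_draws=100)
        assert E.shape == V.shape == (100, data["WT"].n_observed)
        assert np.all(V > 0)


class TestHalfyearDiscrepancy:
    def test_identical_replicates_give_zero(self):
        obs = np.linspace(5, 15, 60)
        wid = np.repeat([0, 1], 30)
        rep = np.tile(obs, (20, 1))
        out = st.halfyear_discrepancy(obs, rep, wid)
        assert np.allclose(out["median"], 0.0)
        assert np.allclose(out["q97_5"], 0.0)

    def test_windows_without_observations_are_skipped(self, small_fit, caplog):
        draws, _, _ = small_fit
        out = st.halfyear_check(draws, n_draws=200, seed=1)
        # two years -> four windows, all observed in this fixture
        assert len(out) == 4

    def test_correct_model_covers_zero(self, small_fit):
        draws, _, _ = small_fit
        out = st.halfyear_check(draws, n_draws=300, seed=2)
        covered = (out["q2_5"] <= 0) & (0 <= out["q97_5"])
        assert covered.mean() >= 0.75


class TestCrossValidation:
    def test_near_noise_free_data_give_small_rmse(self):
        s = st.SimulationScenario(
            years=3, seed=41, sigma_zeta=0.02, sigma_max=0.02, sigma_min=0.02,
            sigma_at=0.4, sigma_q=0.05, at_alpha_sd=0.2, q_alpha_sd=0.05,
            wt_missing=st.MissingSpec(0), at_missing=st.MissingSpec(0),
            q_missing=st.MissingSpec(0))
        data, _ = st.simulate_dataset(s)
        mc = st.McmcConfig(n_chains=2, n_burnin=300, n_keep=300, seed=5)
        cv = st.cross_validate(data, mcmc=mc, n_pred_draws=150, seed=6)
        assert cv.rmse < 0.25

    def test_point_statistic_choice_changes_little(self):
        data, _ = st.simulate_dataset(st.SimulationScenario(
            years=3, seed=43, wt_missing=st.MissingSpec(0.05, 10)))
        mc = st.McmcConfig(n_chains=2, n_burnin=400, n_keep=400, seed=8)
        a = st.cross_validate(data, mcmc=mc, point="mean",
                              n_pred_draws=300, seed=9)
        b = st.cross_validate(data, mcmc=mc, point="median",
                              n_pred_draws=300, seed=9)
        assert abs(a.rmse - b.rmse) / a.rmse < 0.05

    def test_all_missing_tail_rejected(self, small_data):
        data, _ = small_data
        wt = data["WT"]
        T = len(wt)
        k = int(2 * T / 3)
        mask = wt.observed_mask.copy()
        mask[k:] = False
        blanked = st.DailySeries(wt.dates, np.where(mask, wt.values, np.nan),
                                 mask, "WT")
        with pytest.raises(ValueError, match="tail"):
            st.cross_validate({"WT": blanked, "AT": data["AT"],
                               "LOGQ": data["LOGQ"]},
                              mcmc=st.McmcConfig(n_burnin=5, n_keep=5))
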