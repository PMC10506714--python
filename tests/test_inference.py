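"""Tests of priors, the MCMC driver and its reproducibility/validity."""

import numpy as np
import pytest

import streamtemp as st
from streamtemp.core import ModelConfig


@pytest.fixture(scope="module")
def priors_setup(small_data):
    data, _ = small_data
    windows = st.build_windows(data["AT"].dates)
    cfg = ModelConfig(variant="M2", use_discharge=True)
    return data, windows, cfg


class TestPriors:
    def test_defaults_scale_to_the_data(self, priors_setup):
        data, windows, cfg = priors_setup
        priors = st.default_priors(data, windows, cfg)
        loc = np.atleast_1d(priors["alpha_at"].loc)
        # centred near the empirical window means of air temperature
        obs = data["AT"].values[data["AT"].observed_mask]
        assert abs(loc.mean() - obs.mean()) < 3.0
        assert priors["rho_at"].family == "uniform"
        assert priors["sigma_zeta"].family == "halfnormal"

    def test_override_within_bounds_accepted(self, priors_setup):
        data, windows, cfg = priors_setup
        priors = st.default_priors(data, windows, cfg)
        new = priors.replace(rho_at=st.Prior("uniform", -0.5, 0.99))
        assert new["rho_at"].lower == -0.5
        # original object is untouched
        assert priors["rho_at"].lower == -1.0

    def test_sigma_override_with_wrong_support_rejected(self, priors_setup):
        data, windows, cfg = priors_setup
        priors = st.default_priors(data, windows, cfg)
        with pytest.raises(ValueError, match="sigma_zeta"):
            priors.replace(sigma_zeta=st.Prior("normal", -1.0, 1.0))

    def test_rho_bounds_outside_stationarity_rejected(self, priors_setup):
        data, windows, cfg = priors_setup
        priors = st.default_priors(data, windows, cfg)
        with pytest.raises(ValueError, match="rho"):
            priors.replace(rho_at=st.Prior("uniform", -1.5, 0.5))

    def test_unknown_parameter_rejected(self, priors_setup):
        data, windows, cfg = priors_setup
        priors = st.default_priors(data, windows, cfg)
        with pytest.raises(KeyError):
            priors.replace(not_a_parameter=st.Prior("normal", 0, 1))


class TestFit:
    def test_draws_respect_support_invariants(self, small_fit):
        draws, _, _ = small_fit
        assert np.all(draws.get("beta_at") >= 0)
        assert np.all(draws.get("beta_wt") >= 0)
        assert np.all(np.abs(draws.get("rho_at")) < 1)
        assert np.all(np.abs(draws.get("rho_q")) < 1)
        assert np.all(draws.get("max_wt") >= draws.get("min_wt"))
        assert np.all(draws.get("sigma_zeta") > 0)

    def test_latent_draws_present_for_gaps(self, small_fit, small_data):
        draws, _, _ = small_fit
        data, _ = small_data
        n_miss = int((~data["WT"].observed_mask).sum())
        assert draws.arrays["wt_imp"].shape[2] == n_miss
        # latent values look like water temperatures
        assert -5 < draws.get("wt_imp").mean() < 30

    def test_recovers_link_gain(self, small_fit):
        draws, _, truth = small_fit
        assert abs(draws.mean("delta") - truth["delta"]) < 0.1

    def test_convergence_report_covers_all_monitored(self, small_fit):
        draws, report, _ = small_fit
        assert set(report.table["parameter"]) == set(draws.parameter_names())

    def test_seed_reproducibility_bitwise(self, small_data):
        data, _ = small_data
        mc = st.McmcConfig(n_chains=1, n_burnin=40, n_keep=30, seed=12)
        d1, _ = st.fit(data, mcmc=mc, check_convergence=False)
        d2, _ = st.fit(data, mcmc=mc, check_convergence=False)
        for nm in d1.arrays:
            np.testing.assert_array_equal(d1.arrays[nm], d2.arrays[nm])

    def test_no_discharge_fit_has_no_flow_parameters(self, nodis_fit):
        draws, _ = nodis_fit
        for nm in ("gamma", "theta2", "theta2p", "rho_q", "alpha_q", "q_imp"):
            assert nm not in draws.arrays
        assert "delta" in draws.arrays

    def test_missing_series_rejected(self, small_data):
        data, _ = small_data
        with pytest.raises(ValueError, match="LOGQ"):
            st.fit({"WT": data["WT"], "AT": data["AT"]},
                   mcmc=st.McmcConfig(n_burnin=5, n_keep=5))

    def test_mismatched_calendars_rejected(self, small_data):
        data, _ = small_data
        at = data["AT"]
        shifted = st.DailySeries(at.dates[:-30], at.values[:-30],
                                 at.observed_mask[:-30], "AT")
        with pytest.raises(ValueError, match="calendar"):
            st.fit({"WT": data["WT"], "AT": shifted, "LOGQ": data["LOGQ"]},
                   mcmc=st.McmcConfig(n_burnin=5, n_keep=5))

    def test_insufficient_overlap_rejected(self):
        dates = np.arange(np.datetime64("2001-01-01"), np.datetime64("2001-05-01"))
        T = len(dates)
        mask = np.ones(T, bool)
        data = {
            "WT": st.DailySeries(dates, np.full(T, 10.0), mask, "WT"),
            "AT": st.DailySeries(dates, np.full(T, 10.0), mask, "AT"),
        }
        with pytest.raises(ValueError, match="two"):
            st.fit(data, mcmc=st.McmcConfig(n_burnin=5, n_keep=5,
                                            use_discharge=False))

    def test_invalid_mcmc_config_rejected(self):
        with pytest.raises(ValueError):
            st.McmcConfig(n_chains=0)
        with pytest.raises(ValueError):
            st.McmcConfig(variant="M3")


class TestPosteriorDraws:
    def test_flat_names_and_dataframe_shape(self, small_fit):
        draws, _, _ = small_fit
        df = draws.to_dataframe()
        assert len(df) == draws.n_chains * draws.n_kept
        assert set(df.columns) == {"chain", "iteration"} | set(draws.parameter_names())

    def test_quantile_and_mean_consistency(self, small_fit):
        draws, _, _ = small_fit
        med = draws.quantile("delta", 0.5)
        lo, hi = draws.quantile("delta", [0.025, 0.975])
        assert lo <= med <= hi
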