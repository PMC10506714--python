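"""Unit tests of the model's deterministic building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

import streamtemp as st
from streamtemp.core import ModelConfig, ModelState, seasonal_curve


def days(start, stop):
    return np.arange(np.datetime64(start), np.datetime64(stop))


# ---------------------------------------------------------------------------
# calendar windows
# ---------------------------------------------------------------------------


class TestWindows:
    def test_full_year_splits_into_two_half_years(self, year_windows):
        w = year_windows
        assert w.n_windows == 2
        assert [w.window_length(0), w.window_length(1)] == [181, 184]
        assert w.labels == ["2001H1", "2001H2"]
        assert not w.is_partial.any()

    def test_leap_year_has_366_days_and_longer_first_half(self):
        w = st.build_windows(days("2000-01-01", "2001-01-01"))
        assert (w.n_per_year == 366).all()
        assert w.window_length(0) == 182
        assert not w.is_partial.any()

    def test_single_day_is_one_flagged_partial_window(self):
        w = st.build_windows([np.datetime64("2001-03-15")])
        assert w.n_windows == 1
        assert w.is_partial.all()

    def test_every_day_belongs_to_exactly_one_window(self):
        w = st.build_windows(days("1999-11-20", "2002-03-05"))
        counts = np.bincount(w.window_id, minlength=w.n_windows)
        assert counts.sum() == w.n_days
        for y in range(w.n_windows):
            assert counts[y] == w.window_length(y)

    def test_non_consecutive_dates_rejected_with_offender(self):
        d = np.array(["2001-01-01", "2001-01-02", "2001-01-04"],
                     dtype="datetime64[D]")
        with pytest.raises(ValueError, match="2001-01-04"):
            st.build_windows(d)

    def test_duplicate_dates_rejected(self):
        d = np.array(["2001-01-01", "2001-01-01"], dtype="datetime64[D]")
        with pytest.raises(ValueError):
            st.build_windows(d)


# ---------------------------------------------------------------------------
# seasonal signal and extrema reparametrisation
# ---------------------------------------------------------------------------


class TestSeasonalSignal:
    @pytest.mark.parametrize("offset,expected", [
        (0.0, 10.0),        # sin(0) = 0
        (365.0 / 4, 15.0),  # sin(pi/2) = 1
        (3 * 365.0 / 4, 5.0),  # sin(3pi/2) = -1
    ])
    def test_quarter_phase_values(self, year_windows, offset, expected):
        t0 = 20.0
        sp = st.SeasonalParams([10.0, 10.0], [5.0, 5.0], t0)
        # day index of day-of-year t0+offset (doy is 1-based)
        t = int(round(t0 + offset)) - 1
        val = st.seasonal_signal(sp, year_windows, t)
        assert val == pytest.approx(expected, abs=5e-3 * 5)

    def test_periodicity_over_one_year(self):
        w = st.build_windows(days("2001-01-01", "2003-01-01"))
        sp = st.SeasonalParams([8.0] * 4, [4.0] * 4, 123.4)
        t = np.arange(100, 150)
        a = st.seasonal_signal(sp, w, t)
        b = st.seasonal_signal(sp, w, t + 365)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_out_of_range_day_rejected(self, year_windows):
        sp = st.SeasonalParams([1.0, 1.0], [0.0, 0.0], 0.0)
        with pytest.raises(IndexError):
            st.seasonal_signal(sp, year_windows, 400)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            st.SeasonalParams([1.0], [-0.5], 0.0)
        with pytest.raises(ValueError):
            st.SeasonalParams([1.0], [0.5], 400.0)


class TestExtrema:
    def test_simple_conversion(self):
        ep = st.to_extrema(st.SeasonalParams([10.0], [5.0], 0.0))
        assert ep.max_y[0] == 15.0 and ep.min_y[0] == 5.0
        sp = st.from_extrema(st.ExtremaParams([15.0], [5.0]), 0.0)
        assert sp.alpha[0] == 10.0 and sp.beta[0] == 5.0

    def test_zero_amplitude(self):
        ep = st.to_extrema(st.SeasonalParams([7.0], [0.0], 0.0))
        assert ep.max_y[0] == ep.min_y[0] == 7.0

    @given(alpha=hst.floats(-20, 30), beta=hst.floats(0, 15))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_is_exact(self, alpha, beta):
        sp = st.SeasonalParams([alpha], [beta], 12.0)
        back = st.from_extrema(st.to_extrema(sp), sp.t0)
        assert back.alpha[0] == pytest.approx(alpha, abs=1e-12)
        assert back.beta[0] == pytest.approx(beta, abs=1e-12)

    def test_max_below_min_rejected(self):
        with pytest.raises(ValueError):
            st.ExtremaParams([5.0], [15.0])


# ---------------------------------------------------------------------------
# AR(1) residual process
# ---------------------------------------------------------------------------


class TestAR1:
    def test_white_noise_limit_matches_iid_normal_density(self):
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 1.3, size=50)
        p = st.AR1Params(rho=0.0, sigma=1.3)
        expected = sps.norm.logpdf(eps, scale=1.3).sum()
        assert st.ar1_logdensity(eps, p) == pytest.approx(expected, abs=1e-10)

    def test_long_simulation_matches_stationary_variance(self):
        p = st.AR1Params(rho=0.8, sigma=1.0)
        eps = st.ar1_simulate(100_000, p, seed=123)
        assert abs(eps.mean()) < 0.05
        assert eps.var() == pytest.approx(1.0 / (1 - 0.64), rel=0.02)

    def test_zero_path_is_the_density_mode(self):
        p = st.AR1Params(rho=0.6, sigma=0.7)
        rng = np.random.default_rng(1)
        best = st.ar1_logdensity(np.zeros(40), p)
        for _ in range(25):
            assert st.ar1_logdensity(rng.normal(0, 0.3, 40), p) < best

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError):
            st.AR1Params(rho=1.0, sigma=1.0)

    def test_simulation_reproducible(self):
        p = st.AR1Params(rho=0.5, sigma=1.0)
        a = st.ar1_simulate(100, p, seed=9)
        b = st.ar1_simulate(100, p, seed=9)
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# linked regressions
# ---------------------------------------------------------------------------


class TestExtremaRegression:
    def test_intercept_only(self):
        th = st.ThetaParams(8.0, 0.0, 8.0, 0.0)
        mu_max, mu_min = st.wt_extrema_mean(th, 20.0, 5.0)
        assert (mu_max, mu_min) == (8.0, 8.0)

    def test_with_flow_term(self):
        th = st.ThetaParams(2.0, 0.7, 0.0, 0.0, theta2=-0.5)
        mu_max, _ = st.wt_extrema_mean(th, 20.0, 0.0, min_q=0.0, max_q=0.0)
        assert mu_max == pytest.approx(16.0)

    def test_flow_free_variant(self):
        th = st.ThetaParams(0.0, 0.0, 1.0, 0.6)
        _, mu_min = st.wt_extrema_mean(th, 0.0, 5.0)
        assert mu_min == pytest.approx(4.0)

    def test_flow_slopes_without_discharge_rejected(self):
        th = st.ThetaParams(0.0, 0.0, 0.0, 0.0, theta2=0.1)
        with pytest.raises(ValueError):
            st.wt_extrema_mean(th, 1.0, 1.0)


class TestShortTermLink:
    def test_flow_modifier_antiphases_the_seasonal_signal(self):
        t0, n = 110.0, 365
        # seasonal peak: doy = t0 + n/4 -> modifier exactly -1
        assert st.flow_modifier(t0 + n / 4.0, n, t0) == pytest.approx(-1.0, abs=1e-12)
        # seasonal trough: doy = t0 + 3n/4 -> modifier exactly +1
        assert st.flow_modifier(t0 + 3 * n / 4.0, n, t0) == pytest.approx(1.0, abs=1e-12)

    def test_summer_cooling_winter_warming(self):
        link = st.ShortTermLinkParams(delta=0.5, gamma=0.3, sigma_zeta=0.1)
        t0, n = 100.0, 365
        summer = st.short_term_link(link, 2.0, 1.0, t0 + n / 4.0, t0, n)
        winter = st.short_term_link(link, 2.0, 1.0, t0 + 3 * n / 4.0, t0, n)
        assert summer == pytest.approx(0.5 * 2 - 0.3 * 1, abs=1e-9)
        assert winter == pytest.approx(0.5 * 2 + 0.3 * 1, abs=1e-9)

    def test_arithmetic_example(self):
        link = st.ShortTermLinkParams(delta=0.6, gamma=0.5, sigma_zeta=0.1)
        t0, n = 50.0, 365
        out = st.short_term_link(link, 2.0, 1.0, t0 + 3 * n / 4.0, t0, n)
        assert out == pytest.approx(0.6 * 2 + 0.5 * 1, abs=1e-9)

    def test_mismatched_lengths_rejected(self):
        link = st.ShortTermLinkParams(delta=0.6, gamma=0.5)
        with pytest.raises(ValueError):
            st.short_term_link(link, np.zeros(3), np.zeros(4), np.arange(3), 0.0)

    def test_no_flow_series_allowed(self):
        link = st.ShortTermLinkParams(delta=0.6, gamma=0.0)
        out = st.short_term_link(link, np.array([1.0, 2.0]), None, [5, 6], 0.0)
        np.testing.assert_allclose(out, [0.6, 1.2])


# ---------------------------------------------------------------------------
# joint log posterior
# ---------------------------------------------------------------------------


def _toy_setup(gamma=0.5, use_q=True, variant="M2"):
    """A fully observed 30-day dataset and a valid model state."""
    dates = days("2001-06-01", "2001-07-01")
    windows = st.build_windows(dates)
    rng = np.random.default_rng(3)
    T = len(dates)
    at_sp = st.SeasonalParams([12.0], [6.0], 110.0)
    q_sp = st.SeasonalParams([1.5], [0.8], 292.0)
    m_at, _ = seasonal_curve(at_sp.alpha, at_sp.beta, at_sp.t0, windows)
    m_q, _ = seasonal_curve(q_sp.alpha, q_sp.beta, q_sp.t0, windows)
    x_at = m_at + rng.normal(0, 1, T)
    x_q = m_q + rng.normal(0, 0.2, T)
    mx, mn = np.array([17.5]), np.array([8.0])
    wt_t0 = 108.0
    a_w, b_w = (mx + mn) / 2, (mx - mn) / 2
    m_wt, _ = seasonal_curve(a_w, b_w, wt_t0, windows)
    x_wt = m_wt + rng.normal(0, 0.5, T)
    mask = np.ones(T, bool)
    data = {
        "WT": st.DailySeries(dates, x_wt, mask, "WT"),
        "AT": st.DailySeries(dates, x_at, mask, "AT"),
    }
    if use_q:
        data["LOGQ"] = st.DailySeries(dates, x_q, mask, "LOGQ")
    state = ModelState(
        at_seasonal=at_sp,
        at_ar1=st.AR1Params(0.7, 1.1),
        q_seasonal=q_sp if use_q else None,
        q_ar1=st.AR1Params(0.85, 0.2) if use_q else None,
        wt_extrema=st.ExtremaParams(mx, mn),
        wt_t0=wt_t0,
        theta=st.ThetaParams(4.0, 0.75, 2.8, 0.7,
                             -0.4 if use_q else 0.0, 0.4 if use_q else 0.0,
                             0.5, 0.5),
        link=st.ShortTermLinkParams(0.6, gamma if use_q else 0.0, 0.5)
        if variant == "M2" else None,
        wt_ar1=st.AR1Params(0.5, 0.6) if variant == "M1" else None,
        wt_missing=np.array([]), at_missing=np.array([]),
        q_missing=np.array([]) if use_q else None,
    )
    cfg = ModelConfig(variant=variant, use_discharge=use_q)
    return data, windows, state, cfg


def _oracle_logposterior(data, windows, state, cfg):
    """Independent term-by-term evaluation using scipy densities only."""
    m_at, _ = seasonal_curve(state.at_seasonal.alpha, state.at_seasonal.beta,
                             state.at_seasonal.t0, windows)
    eps_at = data["AT"].values - m_at

    def ar1_ll(eps, p):
        ll = sps.norm.logpdf(eps[0], scale=np.sqrt(p.sigma**2 / (1 - p.rho**2)))
        ll += sps.norm.logpdf(eps[1:] - p.rho * eps[:-1], scale=p.sigma).sum()
        return ll

    total = ar1_ll(eps_at, state.at_ar1)
    if cfg.use_discharge:
        m_q, _ = seasonal_curve(state.q_seasonal.alpha, state.q_seasonal.beta,
                                state.q_seasonal.t0, windows)
        eps_q = data["LOGQ"].values - m_q
        total += ar1_ll(eps_q, state.q_ar1)
    th = state.theta
    max_at = state.at_seasonal.alpha + state.at_seasonal.beta
    min_at = state.at_seasonal.alpha - state.at_seasonal.beta
    mu_max = th.theta0 + th.theta1 * max_at
    mu_min = th.theta0p + th.theta1p * min_at
    if cfg.use_discharge:
        mu_max = mu_max + th.theta2 * (state.q_seasonal.alpha - state.q_seasonal.beta)
        mu_min = mu_min + th.theta2p * (state.q_seasonal.alpha + state.q_seasonal.beta)
    total += sps.norm.logpdf(state.wt_extrema.max_y, mu_max, th.sigma_max).sum()
    total += sps.norm.logpdf(state.wt_extrema.min_y, mu_min, th.sigma_min).sum()
    a_w = (state.wt_extrema.max_y + state.wt_extrema.min_y) / 2
    b_w = (state.wt_extrema.max_y - state.wt_extrema.min_y) / 2
    m_wt, _ = seasonal_curve(a_w, b_w, state.wt_t0, windows)
    eps_wt = data["WT"].values - m_wt
    if cfg.variant == "M2":
        doy = windows.day_of_year
        n = windows.n_per_year
        mod = np.sin(2 * np.pi / n * (doy - state.wt_t0 + n / 2))
        mean = state.link.delta * eps_at
        if cfg.use_discharge:
            mean = mean + state.link.gamma * eps_q * mod
        total += sps.norm.logpdf(eps_wt, mean, state.link.sigma_zeta).sum()
    else:
        total += ar1_ll(eps_wt, state.wt_ar1)
    return float(total)


class TestJointLogPosterior:
    def test_matches_independent_term_by_term_oracle(self):
        data, windows, state, cfg = _toy_setup()
        got = st.joint_logposterior(data, windows, state, cfg)
        want = _oracle_logposterior(data, windows, state, cfg)
        assert got == pytest.approx(want, abs=1e-8)

    def test_difference_between_states_matches_oracle(self):
        data, windows, state, cfg = _toy_setup()
        import dataclasses
        state2 = dataclasses.replace(
            state, link=st.ShortTermLinkParams(0.4, 0.3, 0.6),
            at_ar1=st.AR1Params(0.5, 1.4))
        d_got = (st.joint_logposterior(data, windows, state2, cfg)
                 - st.joint_logposterior(data, windows, state, cfg))
        d_want = (_oracle_logposterior(data, windows, state2, cfg)
                  - _oracle_logposterior(data, windows, state, cfg))
        assert d_got == pytest.approx(d_want, abs=1e-8)

    def test_m1_variant_matches_oracle(self):
        data, windows, state, cfg = _toy_setup(variant="M1")
        got = st.joint_logposterior(data, windows, state, cfg)
        want = _oracle_logposterior(data, windows, state, cfg)
        assert got == pytest.approx(want, abs=1e-8)

    def test_gamma_zero_equals_no_flow_structure(self):
        """M2 with gamma = 0 gives the same daily WT law as the flow-free form."""
        data, windows, state, cfg = _toy_setup(gamma=0.0)
        full = st.joint_logposterior(data, windows, state, cfg)
        want = _oracle_logposterior(data, windows, state, cfg)
        assert full == pytest.approx(want, abs=1e-8)

    def test_m2_without_link_collapses_to_m1_white_noise(self):
        """delta = gamma = 0 (M2) equals M1 with rho_WT = 0 and matched sigma."""
        data, windows, state, cfg = _toy_setup(gamma=0.0)
        import dataclasses
        state_m2 = dataclasses.replace(
            state, link=st.ShortTermLinkParams(0.0, 0.0, 0.5))
        state_m1 = dataclasses.replace(
            state, link=None, wt_ar1=st.AR1Params(0.0, 0.5))
        cfg_m1 = ModelConfig(variant="M1", use_discharge=cfg.use_discharge)
        a = st.joint_logposterior(data, windows, state_m2, cfg)
        b = st.joint_logposterior(data, windows, state_m1, cfg_m1)
        assert a == pytest.approx(b, abs=1e-8)

    def test_invalid_structure_returns_minus_inf(self):
        data, windows, state, cfg = _toy_setup()
        cfg_noq = ModelConfig(variant="M2", use_discharge=False)
        data_noq = {k: v for k, v in data.items() if k != "LOGQ"}
        # nonzero flow gain without a discharge series is a rejected state
        assert st.joint_logposterior(data_noq, windows, state, cfg_noq) == -np.inf
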