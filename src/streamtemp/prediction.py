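"""Posterior-predictive water temperature and warming projections.

``predict`` drives the fitted joint posterior through covariate series to
estimate water temperature anywhere the covariates exist: gap filling inside
the training period, hindcasting before it, forecasting after it.  For every
posterior draw the covariates are decomposed over the requested windows
(training windows reuse the draw's window parameters; new windows get their
means/amplitudes sampled from their within-window conditional), water
temperature window extrema follow the extrema regression, and daily values
follow the variant's residual law with all noise terms propagated.

``project_warming`` maps a grid of uniform air-temperature warming offsets
through the extrema regression: a shift of Delta applied to both AT window
extrema moves the annual-mean water temperature by ((theta1 + theta1p)/2) *
Delta per draw, so the posterior of the warming slope carries the full
parameter uncertainty.  Daily deviations are unchanged by a uniform shift,
which is why only the seasonal pathway appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from scipy.signal import lfilter

from .core import DailySeries, WindowIndex, build_windows
from .inference import PosteriorDraws, _mvn_sample, _trunc_normal

logger = logging.getLogger("streamtemp")

__all__ = ["PredictionResult", "WarmingProjection", "predict", "project_warming"]

_QUANTS = {"q2_5": 0.025, "q25": 0.25, "median": 0.5, "q75": 0.75, "q97_5": 0.975}


@dataclass
class PredictionResult:
    """Per-day posterior-predictive summaries of water temperature.

    ``frame`` has one row per target day: ``date, observed, mean, median,
    q2_5, q25, q75, q97_5``.  Days with observed water temperature are passed
    through unchanged and flagged.  ``mean`` averages the conditional mean
    surface over draws (the point prediction used for RMSE); the quantiles
    summarise full predictive draws including observation noise.
    """

    frame: pd.DataFrame
    draws: Optional[np.ndarray] = None  # (n_draws, n_days) predictive draws

    def __post_init__(self) -> None:
        f = self.frame
        bad = (f["q2_5"] > f["median"]) | (f["median"] > f["q97_5"]) \
            | (f["q25"] > f["median"]) | (f["median"] > f["q75"])
        if bool(bad.any()):
            raise AssertionError("predictive quantiles are not ordered")


@dataclass
class WarmingProjection:
    """Posterior of water-temperature warming across an AT warming grid."""

    table: pd.DataFrame  # offset, mean, median, q2_5, q25, q75, q97_5 (+ seasonal)
    slope_draws: np.ndarray  # per-draw annual warming slope (theta1+theta1p)/2
    draws: Optional[np.ndarray] = None  # (n_draws, n_offsets)


def _thin_indices(total: int, n: int) -> np.ndarray:
    if n >= total:
        return np.arange(total)
    return np.unique(np.linspace(0, total - 1, n).astype(int))


class _DrawView:
    """Flat posterior draws with convenient per-draw access."""

    def __init__(self, draws: PosteriorDraws, sel: np.ndarray):
        self.flat = {nm: draws.get(nm)[sel] for nm in draws.arrays}
        self.n = len(sel)

    def __contains__(self, nm):
        return nm in self.flat

    def __getitem__(self, nm):
        return self.flat[nm]


def _sample_new_window(rng, x, obs, s, rho, sig, mu_a, tau_a=0.01, tau_b=0.01):
    """Draw (mean, amplitude) of one unseen window from its conditional.

    Quasi-differences the observed runs under the draw's AR(1) residual law
    (each run restarts from the stationary distribution), then samples the
    conjugate bivariate Normal; a negative amplitude draw is repaired from
    its truncated univariate conditional.
    """
    v0 = sig**2 / (1.0 - rho**2)
    obs_idx = np.flatnonzero(obs)
    if obs_idx.size == 0:
        # no data: prior draw
        a = mu_a + rng.standard_normal() / np.sqrt(tau_a)
        b = abs(rng.standard_normal()) / np.sqrt(tau_b)
        return a, b
    consec = np.zeros(obs_idx.size, dtype=bool)
    consec[1:] = np.diff(obs_idx) == 1
    # rows: run starts (stationary), run continuations (quasi-differenced)
    i = obs_idx
    ca = np.where(consec, 1.0 - rho, 1.0)
    prev = np.clip(i - 1, 0, len(x) - 1)
    cb = np.where(consec, s[i] - rho * s[prev], s[i])
    yv = np.where(consec, x[i] - rho * x[prev], x[i])
    wgt = np.where(consec, 1.0 / sig**2, 1.0 / v0)
    A = np.column_stack([ca, cb])
    P = (A * wgt[:, None]).T @ A + np.diag([tau_a, tau_b])
    rhs = (A * wgt[:, None]).T @ yv + np.array([tau_a * mu_a, 0.0])
    a, b = _mvn_sample(rng, P, rhs)
    if b < 0:
        # repair from the truncated conditional of b given a
        pb = P[1, 1]
        mb = (rhs[1] - P[0, 1] * a) / pb
        b = float(_trunc_normal(rng, mb, 1.0 / np.sqrt(pb), lower=0.0))
    return float(a), float(b)


def _ar1_fill(eps_known: np.ndarray, rho: float, sig: float, rng):
    """Complete a partially known AR(1) path forward in time.

    Known entries are kept; each unknown run is simulated conditionally on
    the last known value before it (or started from the stationary law).
    Returns ``(path, mean_path)`` where the mean path carries the geometric
    decay of the conditional expectation instead of simulated noise.
    """
    T = len(eps_known)
    path = eps_known.copy()
    mean_path = eps_known.copy()
    unknown = ~np.isfinite(eps_known)
    if not unknown.any():
        return path, mean_path
    idx = np.flatnonzero(unknown)
    run_starts = idx[np.concatenate([[True], np.diff(idx) > 1])]
    stat_sd = sig / np.sqrt(1.0 - rho**2)
    for s in run_starts:
        e = s
        while e < T and unknown[e]:
            e += 1
        L = e - s
        z = sig * rng.standard_normal(L)
        if s == 0:
            z[0] = stat_sd * rng.standard_normal()
            sim, _ = lfilter([1.0], [1.0, -rho], z, zi=[0.0])
            mean_path[s:e] = 0.0
        else:
            prev = path[s - 1]
            sim, _ = lfilter([1.0], [1.0, -rho], z, zi=[rho * prev])
            mean_path[s:e] = mean_path[s - 1] * rho ** np.arange(1, L + 1)
        path[s:e] = sim
    return path, mean_path


def predict(
    draws: PosteriorDraws,
    covariates: Mapping[str, DailySeries],
    target_days=None,
    n_draws: int = 500,
    seed: int = 0,
    include_draws: bool = False,
) -> PredictionResult:
    """Posterior-predictive water temperature wherever covariates exist.

    Parameters
    ----------
    draws
        Posterior draws from :func:`streamtemp.fit`.
    covariates
        ``AT`` (and ``LOGQ`` for a discharge model) series covering every
        target day; they may extend before/after the training period for
        hindcasting/forecasting.
    target_days
        Calendar days to predict (default: the full covariate calendar).
    """
    meta = draws.meta
    cfg = meta["config"]
    use_q = cfg.use_discharge
    m2 = cfg.variant == "M2"
    train_windows: WindowIndex = meta["windows"]
    train_wt: DailySeries = meta["data"]["WT"]

    at = covariates["AT"]
    if use_q:
        if "LOGQ" not in covariates:
            raise ValueError("this fit uses discharge; supply a LOGQ series")
        q = covariates["LOGQ"]
        if not np.array_equal(q.dates, at.dates):
            raise ValueError("covariate series must share one calendar")
    pwin = build_windows(at.dates)
    dates = pwin.dates
    if target_days is None:
        target = np.arange(len(dates))
    else:
        td = np.asarray(pd.DatetimeIndex(target_days).values.astype("datetime64[D]"))
        pos = np.searchsorted(dates, td)
        ok = (pos < len(dates)) & (dates[np.clip(pos, 0, len(dates) - 1)] == td)
        if not ok.all():
            missing = td[~ok][:5]
            raise ValueError(f"target days outside covariate coverage: {list(missing)}")
        target = pos

    # covariates must be observed at target days unless inside the training
    # period with latent draws available
    tr_dates = train_windows.dates
    in_train = np.isin(dates, tr_dates)
    tr_pos = np.searchsorted(tr_dates, dates[in_train])

    def _cov_block(series, kind):
        x = series.values.copy()
        obs = series.observed_mask.copy()
        # map training latent draws into this calendar
        lat_name = {"AT": "at_imp", "LOGQ": "q_imp"}[kind]
        miss_tr = meta["missing_idx"][kind]
        fill_pred_idx, fill_lat_idx = [], []
        if miss_tr.size and lat_name in draws.arrays:
            lat_dates = tr_dates[miss_tr]
            sel = np.isin(lat_dates, dates)
            pos = np.searchsorted(dates, lat_dates[sel])
            fill_pred_idx = pos
            fill_lat_idx = np.flatnonzero(sel)
        covered = obs.copy()
        if len(fill_pred_idx):
            covered[fill_pred_idx] = True
        bad = target[~covered[target]]
        if bad.size:
            raise ValueError(
                f"{kind} must cover every target day; missing e.g. "
                f"{list(pd.DatetimeIndex(dates[bad[:5]]).strftime('%Y-%m-%d'))}"
            )
        return x, obs, np.asarray(fill_pred_idx, int), np.asarray(fill_lat_idx, int)

    x_at, obs_at, at_fill_pred, at_fill_lat = _cov_block(at, "AT")
    if use_q:
        x_q, obs_q, q_fill_pred, q_fill_lat = _cov_block(q, "LOGQ")

    # window bookkeeping: match by calendar label
    tr_labels = {lab: y for y, lab in enumerate(train_windows.labels)}
    w_train = np.array([tr_labels.get(lab, -1) for lab in pwin.labels])
    new_w = np.flatnonzero(w_train < 0)

    # WT training pass-through / latent mapping
    wt_obs_pred = np.zeros(len(dates), dtype=bool)
    wt_vals_pred = np.full(len(dates), np.nan)
    sel = in_train.copy()
    wt_obs_pred[sel] = train_wt.observed_mask[tr_pos]
    wt_vals_pred[sel] = train_wt.values[tr_pos]
    wt_miss_tr = meta["missing_idx"]["WT"]

    total = draws.n_chains * draws.n_kept
    use = _thin_indices(total, n_draws)
    dv = _DrawView(draws, use)
    D = dv.n
    rng = np.random.default_rng(seed)

    doy, nyr, wid = pwin.day_of_year.astype(float), pwin.n_per_year.astype(float), pwin.window_id
    Wp = pwin.n_windows
    Tn = len(target)
    mu = np.empty((D, Tn))
    pred = np.empty((D, Tn))
    # per-window empirical means for new-window priors
    emp_mean = np.zeros(Wp)
    for y in new_w:
        sl = slice(pwin.starts[y], pwin.stops[y])
        xa = x_at[sl][obs_at[sl]]
        emp_mean[y] = xa.mean() if xa.size else np.nanmean(x_at[obs_at])

    train_last = tr_dates[-1]
    for d in range(D):
        # --- covariate decomposition over the prediction calendar ----------
        t0a = float(dv["t0_at"][d])
        s_a = np.sin(2.0 * np.pi / nyr * (doy - t0a))
        a_a = np.empty(Wp)
        b_a = np.empty(Wp)
        known = w_train >= 0
        a_a[known] = dv["alpha_at"][d][w_train[known]]
        b_a[known] = dv["beta_at"][d][w_train[known]]
        xa = x_at.copy()
        if at_fill_pred.size:
            xa[at_fill_pred] = dv["at_imp"][d][at_fill_lat]
        for y in new_w:
            sl = slice(pwin.starts[y], pwin.stops[y])
            a_a[y], b_a[y] = _sample_new_window(
                rng, xa[sl], obs_at[sl] | np.isin(np.arange(sl.start, sl.stop), at_fill_pred),
                s_a[sl], float(dv["rho_at"][d]), float(dv["sigma_at"][d]), emp_mean[y])
        eps_a = xa - (a_a[wid] + b_a[wid] * s_a)

        if use_q:
            t0q = float(dv["t0_q"][d])
            s_q = np.sin(2.0 * np.pi / nyr * (doy - t0q))
            a_q = np.empty(Wp)
            b_q = np.empty(Wp)
            a_q[known] = dv["alpha_q"][d][w_train[known]]
            b_q[known] = dv["beta_q"][d][w_train[known]]
            xq = x_q.copy()
            if q_fill_pred.size:
                xq[q_fill_pred] = dv["q_imp"][d][q_fill_lat]
            for y in new_w:
                sl = slice(pwin.starts[y], pwin.stops[y])
                a_q[y], b_q[y] = _sample_new_window(
                    rng, xq[sl], obs_q[sl] | np.isin(np.arange(sl.start, sl.stop), q_fill_pred),
                    s_q[sl], float(dv["rho_q"][d]), float(dv["sigma_q"][d]),
                    float(np.nanmean(xq[obs_q])) if obs_q.any() else 0.0)
            eps_q = xq - (a_q[wid] + b_q[wid] * s_q)

        # --- WT window extrema --------------------------------------------
        mx = np.empty(Wp)
        mn = np.empty(Wp)
        mx[known] = dv["max_wt"][d][w_train[known]]
        mn[known] = dv["min_wt"][d][w_train[known]]
        if new_w.size:
            mu_max = dv["theta0"][d] + dv["theta1"][d] * (a_a[new_w] + b_a[new_w])
            mu_min = dv["theta0p"][d] + dv["theta1p"][d] * (a_a[new_w] - b_a[new_w])
            if use_q:
                mu_max = mu_max + dv["theta2"][d] * (a_q[new_w] - b_q[new_w])
                mu_min = mu_min + dv["theta2p"][d] * (a_q[new_w] + b_q[new_w])
            for _ in range(50):
                mx_new = mu_max + dv["sigma_max"][d] * rng.standard_normal(new_w.size)
                mn_new = mu_min + dv["sigma_min"][d] * rng.standard_normal(new_w.size)
                if np.all(mx_new >= mn_new):
                    break
            else:
                mid = (mx_new + mn_new) / 2.0
                mx_new = np.maximum(mx_new, mid)
                mn_new = np.minimum(mn_new, mid)
            mx[new_w], mn[new_w] = mx_new, mn_new

        t0w = float(dv["t0_wt"][d])
        s_w = np.sin(2.0 * np.pi / nyr * (doy - t0w))
        m_wt = ((mx + mn) / 2.0)[wid] + ((mx - mn) / 2.0)[wid] * s_w

        # --- daily law -----------------------------------------------------
        if m2:
            mean_t = m_wt + dv["delta"][d] * eps_a
            if use_q:
                mean_t = mean_t + dv["gamma"][d] * (-s_w) * eps_q
            mu[d] = mean_t[target]
            pred[d] = mu[d] + dv["sigma_zeta"][d] * rng.standard_normal(Tn)
        else:
            rho_w, sig_w = float(dv["rho_wt"][d]), float(dv["sigma_wt"][d])
            eps_known = np.full(len(dates), np.nan)
            if in_train.any():
                xw_tr = train_wt.values.copy()
                if wt_miss_tr.size and "wt_imp" in dv:
                    xw_tr[wt_miss_tr] = dv["wt_imp"][d]
                eps_known[in_train] = (xw_tr - _train_wt_mean(dv, d, meta))[tr_pos]
            eps_path, eps_mean = _ar1_fill(eps_known, rho_w, sig_w, rng)
            mu[d] = (m_wt + eps_mean)[target]
            pred[d] = (m_wt + eps_path)[target]

    frame = pd.DataFrame({"date": pd.DatetimeIndex(dates[target])})
    frame["observed"] = wt_obs_pred[target]
    frame["mean"] = mu.mean(axis=0)
    for nm, qq in _QUANTS.items():
        frame[nm] = np.quantile(pred, qq, axis=0)
    # pass observed WT days through unchanged
    obs_sel = frame["observed"].to_numpy()
    if obs_sel.any():
        vals = wt_vals_pred[target][obs_sel]
        for nm in ("mean", "median", "q2_5", "q25", "q75", "q97_5"):
            frame.loc[obs_sel, nm] = vals
    return PredictionResult(frame=frame, draws=pred if include_draws else None)


def _train_wt_mean(dv, d, meta):
    """Seasonal WT mean surface of the training calendar for draw ``d``."""
    win: WindowIndex = meta["windows"]
    doy = win.day_of_year.astype(float)
    nyr = win.n_per_year.astype(float)
    s = np.sin(2.0 * np.pi / nyr * (doy - float(dv["t0_wt"][d])))
    a = (dv["max_wt"][d] + dv["min_wt"][d]) / 2.0
    b = (dv["max_wt"][d] - dv["min_wt"][d]) / 2.0
    return a[win.window_id] + b[win.window_id] * s


def project_warming(
    draws: PosteriorDraws,
    at_offsets=None,
    include_draws: bool = False,
) -> WarmingProjection:
    """Project annual-mean WT warming for uniform AT warming offsets.

    Shifting both AT window extrema by Delta moves the WT extrema regression
    means by theta1*Delta (max) and theta1p*Delta (min), hence the annual
    mean (the average of the two) by ((theta1 + theta1p)/2)*Delta — exactly,
    draw by draw; daily deviations are invariant under a uniform shift.
    """
    if at_offsets is None:
        at_offsets = np.arange(0.0, 5.0 + 1e-9, 0.5)
    offsets = np.asarray(at_offsets, dtype=float)
    if offsets.ndim != 1 or len(offsets) == 0:
        raise ValueError("at_offsets must be a 1-d grid")
    if np.any(np.diff(offsets) <= 0):
        raise ValueError("at_offsets must be strictly increasing")
    if offsets.min() <= -10 or offsets.max() >= 10:
        raise ValueError("AT warming offsets outside the sane range (-10, 10) degC")

    th1 = draws.get("theta1")
    th1p = draws.get("theta1p")
    slope = (th1 + th1p) / 2.0
    warm = slope[:, None] * offsets[None, :]
    warm_max = th1[:, None] * offsets[None, :]
    warm_min = th1p[:, None] * offsets[None, :]

    rows = {"offset": offsets, "mean": warm.mean(axis=0)}
    for nm, q in _QUANTS.items():
        rows[nm] = np.quantile(warm, q, axis=0)
    rows["median_max"] = np.quantile(warm_max, 0.5, axis=0)
    rows["median_min"] = np.quantile(warm_min, 0.5, axis=0)
    table = pd.DataFrame(rows)
    return WarmingProjection(
        table=table,
        slope_draws=slope,
        draws=warm if include_draws else None,
    )
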