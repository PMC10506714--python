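"""Model assessment: posterior checks, DIC, cross-validation RMSE.

The assessment suite mirrors the model-comparison workflow for this model
family:

* a chi-square discrepancy computed per posterior draw for the observed and
  for replicated water-temperature data, summarised as a Bayesian p-value
  (values near 0.5 indicate congruency, roughly 0.95 or 0.05 are warnings);
* the Deviance Information Criterion with ``pD = mean(deviance) -
  deviance(at posterior mean)`` (the half-variance estimator is available as
  an option); deviance covers the observed water-temperature days only, so
  the two model variants are compared on the same likelihood scope;
* chronological cross-validation: the first two thirds of the record train
  the model, the last third is forecast from covariates alone and scored by
  RMSE against the held-out observations;
* per-window discrepancies between replicated and observed six-month mean
  water temperature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core import DailySeries, WindowIndex
from .inference import McmcConfig, PosteriorDraws, PriorSpec, fit
from .prediction import predict, _thin_indices

logger = logging.getLogger("streamtemp")

__all__ = [
    "Diagnostics",
    "CrossValidationResult",
    "chi2_discrepancy",
    "dic",
    "posterior_check",
    "deviance_draws",
    "dic_from_fit",
    "halfyear_discrepancy",
    "halfyear_check",
    "cross_validate",
    "evaluate_fit",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class Diagnostics:
    """Fit/forecast summary for one model variant (one diagnostics-table row)."""

    chi2_pvalue: float
    deviance_mean: float
    pD: float
    dic: float
    rmse: Optional[float] = None
    halfyear: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.chi2_pvalue <= 1.0:
            raise ValueError("chi-square Bayesian p-value must lie in [0, 1]")
        if not math.isclose(self.dic, self.deviance_mean + self.pD,
                            rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("DIC must equal deviance_mean + pD")
        if self.rmse is not None and self.rmse < 0:
            raise ValueError("RMSE cannot be negative")

    def row(self, model: str) -> dict:
        return {
            "model": model,
            "RMSE": self.rmse,
            "chi2_pvalue": self.chi2_pvalue,
            "deviance": self.deviance_mean,
            "pD": self.pD,
            "DIC": self.dic,
        }


# ---------------------------------------------------------------------------
# low-level statistics (shape-checked, oracle-testable)
# ---------------------------------------------------------------------------


def chi2_discrepancy(
    wt_obs: np.ndarray,
    expectations: np.ndarray,
    variances: np.ndarray,
    rng=None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Chi-square discrepancies of observed and replicated data per draw.

    ``expectations`` and ``variances`` hold the conditional mean/variance of
    every observed day given each posterior draw (shape ``(n_draws,
    n_days)``; variances may broadcast).  Replicates are drawn from the same
    conditional law.  Returns ``(chi2_obs, chi2_rep, p_value)`` with
    ``p_value`` the fraction of draws where the replicated discrepancy
    exceeds the observed one.
    """
    wt_obs = np.asarray(wt_obs, dtype=float)
    E = np.atleast_2d(np.asarray(expectations, dtype=float))
    V = np.broadcast_to(np.asarray(variances, dtype=float), E.shape)
    if wt_obs.ndim != 1 or E.shape[1] != wt_obs.size:
        raise ValueError("expectations must be (n_draws, n_obs_days)")
    if np.any(V <= 0):
        raise ValueError("zero variance at an observed day: chi-square undefined")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    chi2_obs = np.sum((wt_obs[None, :] - E) ** 2 / V, axis=1)
    rep = E + np.sqrt(V) * rng.standard_normal(E.shape)
    chi2_rep = np.sum((rep - E) ** 2 / V, axis=1)
    p = float(np.mean(chi2_rep > chi2_obs))
    return chi2_obs, chi2_rep, p


def dic(
    deviance_values: np.ndarray,
    deviance_at_mean: float,
    pd_variant: str = "mean",
) -> Tuple[float, float, float]:
    """Deviance Information Criterion from per-draw deviances.

    ``pd_variant="mean"`` uses the plug-in complexity ``pD = mean(D) -
    D(posterior mean)``; ``"half_var"`` uses ``var(D)/2``.  Returns
    ``(deviance_mean, pD, DIC)`` with ``DIC = deviance_mean + pD``.  A DIC
    reduction of about five points is conventionally taken as meaningful.
    """
    devs = np.asarray(deviance_values, dtype=float)
    if devs.ndim != 1 or devs.size < 2:
        raise ValueError("need at least two deviance draws")
    dbar = float(devs.mean())
    if pd_variant == "mean":
        p_d = dbar - float(deviance_at_mean)
    elif pd_variant == "half_var":
        p_d = float(devs.var(ddof=1)) / 2.0
    else:
        raise ValueError("pd_variant must be 'mean' or 'half_var'")
    return dbar, p_d, dbar + p_d


# ---------------------------------------------------------------------------
# conditional moments of observed WT given each draw
# ---------------------------------------------------------------------------


def _flat_subset(draws: PosteriorDraws, n_draws: Optional[int]):
    total = draws.n_chains * draws.n_kept
    sel = _thin_indices(total, n_draws or total)
    return {nm: draws.get(nm)[sel] for nm in draws.arrays}, len(sel)


def _mean_draw(flat: dict) -> dict:
    return {nm: np.atleast_1d(a.mean(axis=0))[None] if a.ndim > 1
            else np.array([a.mean()]) for nm, a in flat.items()}


def conditional_moments(draws: PosteriorDraws, n_draws: Optional[int] = 1000,
                        flat: Optional[dict] = None):
    """Per-draw conditional mean and variance of WT at its observed days.

    For the covariate-linked variant the conditional law given a draw is
    Normal(seasonal + delta*eps_AT + gamma*modifier*eps_Q, sigma_zeta^2); for
    the AR(1) variant it is the one-step law Normal(seasonal + rho*eps[t-1],
    sigma^2) (stationary at the first day).  Returns ``(E, V, obs_idx)``.
    """
    meta = draws.meta
    cfg = meta["config"]
    win: WindowIndex = meta["windows"]
    data = meta["data"]
    wt: DailySeries = data["WT"]
    obs_idx = np.flatnonzero(wt.observed_mask)
    if flat is None:
        flat, _ = _flat_subset(draws, n_draws)
    D = next(iter(flat.values())).shape[0]
    T = win.n_days
    doy = win.day_of_year.astype(float)[None, :]
    nyr = win.n_per_year.astype(float)[None, :]
    wid = win.window_id

    def seasonal(alpha, beta, t0):
        s = np.sin(2.0 * np.pi / nyr * (doy - t0[:, None]))
        return alpha[:, wid] + beta[:, wid] * s, s

    def complete(series_key, kind):
        base = np.broadcast_to(data[kind].values, (D, T)).copy()
        miss = meta["missing_idx"][kind]
        if miss.size:
            if series_key not in flat:
                raise ValueError(
                    f"latent draws for {kind} gaps are required (keep_latent=True)")
            base[:, miss] = flat[series_key]
        return base

    a_w = (flat["max_wt"] + flat["min_wt"]) / 2.0
    b_w = (flat["max_wt"] - flat["min_wt"]) / 2.0
    m_wt, s_w = seasonal(a_w, b_w, flat["t0_wt"])

    x_at = complete("at_imp", "AT")
    m_at, _ = seasonal(flat["alpha_at"], flat["beta_at"], flat["t0_at"])
    eps_at = x_at - m_at

    if cfg.variant == "M2":
        E = m_wt + flat["delta"][:, None] * eps_at
        if cfg.use_discharge:
            x_q = complete("q_imp", "LOGQ")
            m_q, _ = seasonal(flat["alpha_q"], flat["beta_q"], flat["t0_q"])
            E = E + flat["gamma"][:, None] * (-s_w) * (x_q - m_q)
        V = np.broadcast_to((flat["sigma_zeta"] ** 2)[:, None],
                            (D, obs_idx.size)).copy()
        E = E[:, obs_idx]
    else:
        x_wt = complete("wt_imp", "WT")
        eps_wt = x_wt - m_wt
        rho = flat["rho_wt"][:, None]
        sig2 = (flat["sigma_wt"] ** 2)[:, None]
        prev = np.clip(obs_idx - 1, 0, T - 1)
        E = m_wt[:, obs_idx] + rho * eps_wt[:, prev]
        V = np.broadcast_to(sig2, (D, obs_idx.size)).copy()
        first = obs_idx == 0
        if first.any():
            E[:, first] = m_wt[:, obs_idx[first]]
            V[:, first] = sig2 / (1.0 - rho**2)
    return E, V, obs_idx


# ---------------------------------------------------------------------------
# drivers operating on a fit
# ---------------------------------------------------------------------------


def posterior_check(draws: PosteriorDraws, n_draws: int = 1000, seed: int = 0) -> float:
    """Bayesian p-value of the chi-square discrepancy for a fitted model."""
    E, V, obs_idx = conditional_moments(draws, n_draws)
    wt = draws.meta["data"]["WT"]
    _, _, p = chi2_discrepancy(wt.values[obs_idx], E, V,
                               np.random.default_rng(seed))
    return p


def deviance_draws(draws: PosteriorDraws, n_draws: Optional[int] = 1000):
    """Per-draw deviance (-2 log-likelihood of observed WT days) and the
    deviance at the posterior mean of all parameters and latent values."""
    flat, _ = _flat_subset(draws, n_draws)
    wt = draws.meta["data"]["WT"]

    def dev_from(flat_like):
        E, V, obs_idx = conditional_moments(draws, None, flat=flat_like)
        y = wt.values[obs_idx][None, :]
        ll = -0.5 * (_LOG2PI + np.log(V) + (y - E) ** 2 / V)
        return -2.0 * ll.sum(axis=1)

    devs = dev_from(flat)
    dev_mean = float(dev_from(_mean_draw(flat))[0])
    return devs, dev_mean


def dic_from_fit(draws: PosteriorDraws, n_draws: Optional[int] = 1000,
                 pd_variant: str = "mean"):
    devs, dev_at_mean = deviance_draws(draws, n_draws)
    return dic(devs, dev_at_mean, pd_variant)


def halfyear_discrepancy(
    wt_obs: np.ndarray,
    replicated: np.ndarray,
    window_id: np.ndarray,
    labels=None,
) -> pd.DataFrame:
    """Posterior of replicated-minus-observed six-month mean WT per window.

    Only observed days enter both averages; windows without observed days are
    skipped with a warning.  Returns one row per window with the posterior
    median and 50/95% intervals of the discrepancy.
    """
    wt_obs = np.asarray(wt_obs, dtype=float)
    rep = np.atleast_2d(np.asarray(replicated, dtype=float))
    window_id = np.asarray(window_id)
    if rep.shape[1] != wt_obs.size or window_id.size != wt_obs.size:
        raise ValueError("replicated draws and window ids must match wt_obs")
    rows = []
    for y in np.unique(window_id):
        sel = window_id == y
        if not sel.any():
            continue
        disc = rep[:, sel].mean(axis=1) - wt_obs[sel].mean()
        lab = labels[y] if labels is not None else y
        rows.append({
            "window": lab,
            "median": float(np.median(disc)),
            "q2_5": float(np.quantile(disc, 0.025)),
            "q25": float(np.quantile(disc, 0.25)),
            "q75": float(np.quantile(disc, 0.75)),
            "q97_5": float(np.quantile(disc, 0.975)),
        })
    return pd.DataFrame(rows)


def halfyear_check(draws: PosteriorDraws, n_draws: int = 1000,
                   seed: int = 0) -> pd.DataFrame:
    """Replicated-vs-observed six-month mean discrepancies for a fitted model."""
    E, V, obs_idx = conditional_moments(draws, n_draws)
    rng = np.random.default_rng(seed)
    rep = E + np.sqrt(V) * rng.standard_normal(E.shape)
    win: WindowIndex = draws.meta["windows"]
    wt = draws.meta["data"]["WT"]
    all_windows = np.arange(win.n_windows)
    present = np.unique(win.window_id[obs_idx])
    skipped = np.setdiff1d(all_windows, present)
    if skipped.size:
        logger.warning("windows with no observed WT skipped: %s",
                       [win.labels[y] for y in skipped])
    return halfyear_discrepancy(wt.values[obs_idx], rep,
                                win.window_id[obs_idx], win.labels)


@dataclass
class CrossValidationResult:
    rmse: float
    split_date: np.datetime64
    n_eval: int
    frame: pd.DataFrame  # per-day forecasts over the held-out tail
    draws: PosteriorDraws


def _slice_series(s: DailySeries, start: int, stop: int) -> DailySeries:
    return DailySeries(s.dates[start:stop], s.values[start:stop],
                       s.observed_mask[start:stop], s.kind)


def cross_validate(
    data: Mapping[str, DailySeries],
    priors: Optional[PriorSpec] = None,
    mcmc: Optional[McmcConfig] = None,
    train_fraction: float = 2.0 / 3.0,
    point: str = "mean",
    n_pred_draws: int = 400,
    seed: int = 0,
) -> CrossValidationResult:
    """Chronological hold-out: train on the head, forecast the tail.

    Splits at ``floor(train_fraction * T)`` days, fits on the head, predicts
    the tail from covariates alone and reports the RMSE between observed WT
    and the posterior-``point`` prediction over observed tail days.
    """
    if not 0.1 < train_fraction < 0.95:
        raise ValueError("train_fraction out of range")
    if point not in ("mean", "median"):
        raise ValueError("point must be 'mean' or 'median'")
    mcmc = mcmc or McmcConfig()
    wt = data["WT"]
    T = len(wt)
    k = int(math.floor(train_fraction * T))
    head = {kind: _slice_series(s, 0, k) for kind, s in data.items()}
    tail_wt = _slice_series(wt, k, T)
    if tail_wt.n_observed == 0:
        raise ValueError("no observed water temperature in the held-out tail")

    draws, _ = fit(head, priors=priors, mcmc=mcmc, check_convergence=False)

    # forecast every tail day whose covariates are observed
    cov_ok = data["AT"].observed_mask.copy()
    if mcmc.use_discharge:
        cov_ok &= data["LOGQ"].observed_mask
    tail_idx = np.arange(k, T)
    covered = tail_idx[cov_ok[k:]]
    dropped = tail_idx.size - covered.size
    if dropped:
        logger.info("cross-validation: %d tail days lack covariates and are "
                    "not forecast", dropped)
    covs = {"AT": data["AT"]}
    if mcmc.use_discharge:
        covs["LOGQ"] = data["LOGQ"]
    result = predict(draws, covs, target_days=wt.dates[covered],
                     n_draws=n_pred_draws, seed=seed)

    obs_sel = wt.observed_mask[covered]
    y = wt.values[covered][obs_sel]
    yhat = result.frame[point].to_numpy()[obs_sel]
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return CrossValidationResult(
        rmse=rmse,
        split_date=wt.dates[k],
        n_eval=int(obs_sel.sum()),
        frame=result.frame,
        draws=draws,
    )


def evaluate_fit(draws: PosteriorDraws, rmse: Optional[float] = None,
                 n_draws: int = 1000, seed: int = 0,
                 include_halfyear: bool = True) -> Diagnostics:
    """Posterior check, DIC and (optionally supplied) cross-validation RMSE."""
    p = posterior_check(draws, n_draws=n_draws, seed=seed)
    dbar, p_d, dic_val = dic_from_fit(draws, n_draws=n_draws)
    hy = halfyear_check(draws, n_draws=n_draws, seed=seed) if include_halfyear else None
    return Diagnostics(chi2_pvalue=p, deviance_mean=dbar, pD=p_d, dic=dic_val,
                       rmse=rmse, halfyear=hy)
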