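"""MCMC fitting of the hierarchical stream-temperature model.

The joint posterior factorises into conditionally Gaussian blocks, so the
sampler is a Metropolis-within-Gibbs scheme built around exact conjugate
updates (the classic strategy of Gibbs-based engines for this model family):

* per-window means/amplitudes of each series — conjugate Normal (amplitudes
  truncated at zero), updated in an even/odd window checkerboard because the
  AR(1) residuals couple adjacent windows through the quasi-differences;
* water-temperature window extrema — conjugate Normal with the extrema
  regression acting as their hierarchical prior, truncated to max >= min;
* regression coefficients theta and the daily gains delta/gamma — exact
  multivariate Normal draws;
* innovation SDs and autocorrelations — univariate slice sampling (cheap:
  their conditionals depend on the data only through precomputed sums);
* the phases t0 — random-walk Metropolis on the circle with Robbins-Monro
  scale adaptation during burn-in;
* latent values at unobserved days — drawn from their exact Gaussian full
  conditionals (simultaneously with the fit, as in the original model).

Chains are deterministic given ``McmcConfig.seed``; split-R-hat and bulk ESS
come from arviz.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .core import (
    AR1Params,
    DailySeries,
    ExtremaParams,
    ModelConfig,
    ModelState,
    SeasonalParams,
    ShortTermLinkParams,
    ThetaParams,
    WindowIndex,
    build_windows,
    flow_modifier,
    joint_logposterior,
)
from .priors import Prior, PriorSpec, default_priors, _empirical_sine_stats

logger = logging.getLogger("streamtemp")

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "fit",
    "default_priors",
    "PriorSpec",
    "Prior",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class McmcConfig:
    """Sampler settings.

    The reference preset (:meth:`paper`) runs three chains with a burn-in of
    10000, keeping 10000 draws per chain after thinning by 25.  The desk
    preset (:meth:`desk`, the default) is sized for interactive work and
    testing: three chains, burn-in 2000, 2000 kept, no thinning.
    """

    n_chains: int = 3
    n_burnin: int = 2000
    n_keep: int = 2000
    thin: int = 1
    seed: int = 0
    variant: str = "M2"
    use_discharge: bool = True
    share_intercept: bool = False
    keep_latent: bool = True

    def __post_init__(self) -> None:
        for nm in ("n_chains", "n_burnin", "n_keep", "thin"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be a positive count")
        if self.variant not in ("M1", "M2"):
            raise ValueError("variant must be 'M1' or 'M2'")

    @classmethod
    def desk(cls, **kw) -> "McmcConfig":
        return cls(n_chains=3, n_burnin=2000, n_keep=2000, thin=1, **kw)

    @classmethod
    def paper(cls, **kw) -> "McmcConfig":
        return cls(n_chains=3, n_burnin=10000, n_keep=10000, thin=25, **kw)

    @property
    def model_config(self) -> ModelConfig:
        return ModelConfig(
            variant=self.variant,
            use_discharge=self.use_discharge,
            share_intercept=self.share_intercept,
        )


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------


class PosteriorDraws:
    """Labelled MCMC draws: (chain, iteration) per parameter.

    Scalar parameters map to arrays of shape ``(n_chains, n_kept)``; window
    blocks and latent imputations to ``(n_chains, n_kept, k)`` with flat
    names like ``alpha_at[3]`` or ``wt_imp[1996-02-07]``.
    """

    def __init__(self, arrays: Dict[str, np.ndarray], labels: Dict[str, list],
                 meta: dict):
        self.arrays = arrays
        self.labels = labels  # component labels for 3-d blocks
        self.meta = meta  # windows, data, config(McmcConfig), priors, ...
        for nm, a in arrays.items():
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite posterior draws for {nm}")

    # -- basic access ------------------------------------------------------
    @property
    def n_chains(self) -> int:
        return next(iter(self.arrays.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.arrays.values())).shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self.arrays

    def get(self, name: str) -> np.ndarray:
        """Draws for a base parameter, flattened across chains."""
        a = self.arrays[name]
        return a.reshape(-1, *a.shape[2:])

    def mean(self, name: str):
        return self.get(name).mean(axis=0)

    def quantile(self, name: str, q):
        return np.quantile(self.get(name), q, axis=0)

    def flat(self) -> Dict[str, np.ndarray]:
        out = {}
        for nm, a in self.arrays.items():
            if a.ndim == 2:
                out[nm] = a
            else:
                for k in range(a.shape[2]):
                    out[f"{nm}[{self.labels[nm][k]}]"] = a[:, :, k]
        return out

    def parameter_names(self) -> list:
        return list(self.flat())

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: one row per (chain, iteration), one column per parameter."""
        flat = self.flat()
        C, N = self.n_chains, self.n_kept
        cols = {
            "chain": np.repeat(np.arange(C), N),
            "iteration": np.tile(np.arange(N), C),
        }
        for nm, a in flat.items():
            cols[nm] = a.reshape(-1)
        return pd.DataFrame(cols)

    def to_inference_data(self):
        import arviz as az

        return az.from_dict({nm: a for nm, a in self.arrays.items()})


@dataclass
class ConvergenceReport:
    """Split-R-hat / effective sample size per monitored parameter."""

    table: pd.DataFrame  # columns: parameter, rhat, ess, ok
    rhat_threshold: float = 1.1
    ess_threshold: float = 100.0

    @property
    def all_ok(self) -> bool:
        return bool(self.table["ok"].all())

    def failures(self) -> pd.DataFrame:
        return self.table[~self.table["ok"]]


def _convergence_report(draws: "PosteriorDraws") -> ConvergenceReport:
    import arviz as az

    idata = az.from_dict({nm: a for nm, a in draws.arrays.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    single_chain = draws.n_chains < 2
    rows = []
    for nm, a in draws.arrays.items():
        r = np.atleast_1d(np.asarray(rhat[nm]))
        e = np.atleast_1d(np.asarray(ess[nm]))
        labels = draws.labels.get(nm)
        for k in range(r.size):
            pname = nm if a.ndim == 2 else f"{nm}[{labels[k]}]"
            rv, ev = float(r.flat[k]), float(e.flat[k])
            ok = (ev >= 100.0) and (single_chain or rv <= 1.1)
            rows.append((pname, rv, ev, ok))
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "ok"])
    return ConvergenceReport(table=table)


# ---------------------------------------------------------------------------
# generic sampling utilities
# ---------------------------------------------------------------------------


def _slice_sample(x0, logf, rng, w=0.5, lower=-np.inf, upper=np.inf, max_steps=30):
    """Univariate slice sampler (stepping out + shrinkage, Neal 2003)."""
    f0 = logf(x0)
    y = f0 - rng.exponential()
    u = rng.uniform()
    lo = x0 - w * u
    hi = lo + w
    for _ in range(max_steps):
        if lo <= lower or logf(lo) < y:
            break
        lo -= w
    for _ in range(max_steps):
        if hi >= upper or logf(hi) < y:
            break
        hi += w
    lo, hi = max(lo, lower), min(hi, upper)
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # numerically degenerate slice; keep current point


def _trunc_normal(rng, mean, sd, lower=None, upper=None):
    """Vectorised truncated-normal draws via the inverse CDF."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if lower is None:
        lo = np.zeros(np.shape(mean))
    else:
        lo = special.ndtr((np.asarray(lower, float) - mean) / sd)
    if upper is None:
        hi = np.ones(np.shape(mean))
    else:
        hi = special.ndtr((np.asarray(upper, float) - mean) / sd)
    u = rng.uniform(size=np.shape(mean))
    p = np.clip(lo + u * (hi - lo), 1e-14, 1.0 - 1e-14)
    return mean + sd * special.ndtri(p)


def _mvn_sample(rng, precision, b):
    """Draw from N(P^-1 b, P^-1) via Cholesky of the precision matrix."""
    L = np.linalg.cholesky(precision)
    mean = np.linalg.solve(precision, b)
    z = rng.standard_normal(len(b))
    return mean + np.linalg.solve(L.T, z)


def _window_quad_stats(d, eps, rho, sig2, v0, ws, wid):
    """Per-window precision/cross sums of the AR(1) quasi-difference terms.

    ``d`` is the day-level design column of the per-window scalar being
    updated (ones for a window mean, the seasonal sine for an amplitude).
    Returns ``(S2, S1)`` such that the conditional given the current residual
    vector ``eps`` (which already reflects the current value ``phi``) is
    Normal with precision ``prior_prec + S2`` and mean
    ``(prior_prec*prior_mean + phi*S2 - S1) / precision``.
    """
    T = len(eps)
    qd = np.zeros(T)
    qd[1:] = eps[1:] - rho * eps[:-1]
    same = np.zeros(T, dtype=bool)
    same[1:] = wid[1:] == wid[:-1]
    h = np.zeros(T)
    h[1:] = -d[1:] + rho * np.where(same[1:], d[:-1], 0.0)
    S2 = np.add.reduceat(h * h, ws) / sig2
    S1 = np.add.reduceat(h * qd, ws) / sig2
    if len(ws) > 1:  # boundary terms: first day of next window
        tb = ws[1:]
        hb = rho * d[tb - 1]
        S2[:-1] += hb * hb / sig2
        S1[:-1] += hb * qd[tb] / sig2
    S2[0] += d[0] * d[0] / v0
    S1[0] += -d[0] * eps[0] / v0
    return S2, S1


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------


class _Series:
    """Mutable per-series sampler block (complete data + seasonal state)."""

    __slots__ = ("x", "miss", "a", "b", "t0", "rho", "sig", "s", "m", "eps",
                 "mu0", "tau0", "tau_b", "rho_lo", "rho_hi", "hn_sig",
                 "t0_lo", "t0_hi", "mh_scale", "mh_acc", "mh_n")

    def __init__(self):
        self.mh_scale = 3.0
        self.mh_acc = 0
        self.mh_n = 0


class _Gibbs:
    def __init__(self, data, windows: WindowIndex, priors: PriorSpec,
                 mcmc: McmcConfig):
        self.windows = windows
        self.priors = priors
        self.mcmc = mcmc
        self.cfg = mcmc.model_config
        self.use_q = self.cfg.use_discharge
        self.m2 = self.cfg.variant == "M2"
        self.T = windows.n_days
        self.W = windows.n_windows
        self.ws = windows.starts
        self.wid = windows.window_id
        self.doy = windows.day_of_year.astype(float)
        self.nyr = windows.n_per_year.astype(float)
        self.even = np.arange(0, self.W, 2)
        self.odd = np.arange(1, self.W, 2)

        self.wt_obs = data["WT"].observed_mask.copy()
        self.wt_vals = data["WT"].values
        self.at_obs = data["AT"].observed_mask.copy()
        self.at_vals = data["AT"].values
        if self.use_q:
            self.q_obs = data["LOGQ"].observed_mask.copy()
            self.q_vals = data["LOGQ"].values

        self.wt_miss_idx = np.flatnonzero(~self.wt_obs)
        self.at_miss_idx = np.flatnonzero(~self.at_obs)
        self.q_miss_idx = np.flatnonzero(~self.q_obs) if self.use_q else np.array([], int)

        # theta prior precision
        p = priors["theta1"]
        self.theta_tau = 1.0 / float(p.scale) ** 2
        p = priors["delta"]
        self.link_tau = 1.0 / float(p.scale) ** 2
        self.hn_sigma_max = float(priors["sigma_max"].scale)
        self.hn_sigma_min = float(priors["sigma_min"].scale)
        if self.m2:
            self.hn_sigma_zeta = float(priors["sigma_zeta"].scale)
        else:
            self.hn_sigma_wt = float(priors["sigma_wt"].scale)
            self.rho_wt_bounds = (priors["rho_wt"].lower, priors["rho_wt"].upper)
        self.t0_wt_bounds = (priors["t0_wt"].lower, priors["t0_wt"].upper)

    # ---------------- initialisation -----------------------------------
    def _init_series(self, kind, vals, obs, prefix, rng, jitter):
        ser = _Series()
        p_alpha = self.priors.get(f"alpha_{prefix}") if prefix != "wt" else None
        alpha0, t00, rsd, beta0 = self._sine_stats[prefix]
        ser.a = alpha0 + jitter * 0.3 * rng.standard_normal(self.W)
        ser.b = np.abs(beta0 + jitter * 0.3 * rng.standard_normal(self.W))
        n_max = float(self.nyr.max())
        ser.t0 = (t00 + jitter * 5.0 * rng.standard_normal()) % n_max
        x = vals.copy()
        ser.miss = np.flatnonzero(~obs)
        ser.s = np.sin(2.0 * np.pi / self.nyr * (self.doy - ser.t0))
        ser.m = ser.a[self.wid] + ser.b[self.wid] * ser.s
        x[~obs] = ser.m[~obs]
        ser.x = x
        ser.eps = ser.x - ser.m
        # residual autocorrelation from observed pairs
        e = ser.eps.copy()
        e[~obs] = np.nan
        pair = ~np.isnan(e[1:]) & ~np.isnan(e[:-1])
        if pair.sum() > 10:
            r = float(np.corrcoef(e[1:][pair], e[:-1][pair])[0, 1])
        else:
            r = 0.3
        ser.rho = float(np.clip(r + jitter * 0.05 * rng.standard_normal(), -0.9, 0.9))
        ser.sig = max(rsd * math.sqrt(max(1.0 - ser.rho**2, 0.05)), 1e-2)
        ser.sig *= math.exp(jitter * 0.1 * rng.standard_normal())
        if prefix != "wt":
            ser.mu0 = np.asarray(p_alpha.loc, float) * np.ones(self.W)
            ser.tau0 = 1.0 / float(p_alpha.scale) ** 2
            ser.tau_b = 1.0 / float(self.priors[f"beta_{prefix}"].scale) ** 2
            pr = self.priors[f"rho_{prefix}"]
            ser.rho_lo, ser.rho_hi = pr.lower, pr.upper
            ser.rho = float(np.clip(ser.rho, ser.rho_lo + 1e-3, ser.rho_hi - 1e-3))
            ser.hn_sig = float(self.priors[f"sigma_{prefix}"].scale)
            pt = self.priors[f"t0_{prefix}"]
            ser.t0_lo, ser.t0_hi = pt.lower, pt.upper
        return ser

    def init_state(self, rng, jitter=1.0) -> dict:
        self._sine_stats = {}
        for prefix, vals, obs in (("at", self.at_vals, self.at_obs),
                                  ("wt", self.wt_vals, self.wt_obs)):
            ds = DailySeries(self.windows.dates, vals, obs,
                             {"at": "AT", "wt": "WT"}[prefix])
            self._sine_stats[prefix] = _empirical_sine_stats(ds, self.windows)
        if self.use_q:
            ds = DailySeries(self.windows.dates, self.q_vals, self.q_obs, "LOGQ")
            self._sine_stats["q"] = _empirical_sine_stats(ds, self.windows)

        st: dict = {}
        st["at"] = self._init_series("AT", self.at_vals, self.at_obs, "at", rng, jitter)
        if self.use_q:
            st["q"] = self._init_series("LOGQ", self.q_vals, self.q_obs, "q", rng, jitter)
        wt = self._init_series("WT", self.wt_vals, self.wt_obs, "wt", rng, jitter)
        st["wt"] = wt
        wt.b = np.maximum(wt.b, 0.05)
        st["mx"] = wt.a + wt.b
        st["mn"] = wt.a - wt.b

        # extrema regression from initial window values; ridge-regularised so
        # that few, collinear windows cannot produce wild starting slopes
        # (a tight, badly-placed regression would distort every other block)
        X = self._theta_design(st)
        Xm = self._theta_design_min(st)
        k = X.shape[1]
        ridge = np.eye(k)
        coef_max = np.linalg.solve(X.T @ X + ridge, X.T @ st["mx"])
        coef_min = np.linalg.solve(Xm.T @ Xm + ridge, Xm.T @ st["mn"])
        st["th_max"] = coef_max + jitter * 0.1 * rng.standard_normal(k)
        st["th_min"] = coef_min + jitter * 0.1 * rng.standard_normal(k)
        st["sigma_max"] = max(float(np.std(st["mx"] - X @ coef_max)), 0.4)
        st["sigma_min"] = max(float(np.std(st["mn"] - Xm @ coef_min)), 0.4)

        if self.m2:
            f1 = st["at"].eps
            preds = [f1]
            if self.use_q:
                mod = flow_modifier(self.doy, self.nyr, wt.t0)
                preds.append(mod * st["q"].eps)
            A = np.column_stack(preds)
            sel = self.wt_obs & self.at_obs
            if self.use_q:
                sel &= self.q_obs
            coef, *_ = np.linalg.lstsq(A[sel], wt.eps[sel], rcond=None)
            st["delta"] = float(coef[0]) + jitter * 0.1 * rng.standard_normal()
            st["gamma"] = (float(coef[1]) if self.use_q else 0.0)
            if self.use_q:
                st["gamma"] += jitter * 0.1 * rng.standard_normal()
            resid = wt.eps[sel] - A[sel] @ coef
            st["sigma_zeta"] = max(float(np.std(resid)), 5e-2)
        st["wt_mh"] = [3.0, 0, 0]  # scale, accepted, proposed for t0_wt
        st["joint_mh"] = [3.0, 0, 0]  # common phase shift of all series
        return st

    # ---------------- shared pieces -------------------------------------
    def _theta_design(self, st) -> np.ndarray:
        at = st["at"]
        cols_max = [np.ones(self.W), at.a + at.b]
        if self.use_q:
            q = st["q"]
            cols_max.append(q.a - q.b)
        return np.column_stack(cols_max)

    def _theta_design_min(self, st) -> np.ndarray:
        at = st["at"]
        cols = [np.ones(self.W), at.a - at.b]
        if self.use_q:
            q = st["q"]
            cols.append(q.a + q.b)
        return np.column_stack(cols)

    def _mu_extrema(self, st):
        mu_max = self._theta_design(st) @ st["th_max"]
        mu_min = self._theta_design_min(st) @ st["th_min"]
        return mu_max, mu_min

    def _wt_seasonal(self, st):
        wt = st["wt"]
        a = (st["mx"] + st["mn"]) / 2.0
        b = (st["mx"] - st["mn"]) / 2.0
        return a[self.wid] + b[self.wid] * wt.s

    def _zeta_resid(self, st):
        """Current white-noise residual of the daily WT equation (M2)."""
        wt = st["wt"]
        r = wt.x - self._wt_seasonal(st) - st["delta"] * st["at"].eps
        if self.use_q:
            r -= st["gamma"] * (-wt.s) * st["q"].eps
        return r

    # the flow modifier sin(2pi/n (doy - t0 + n/2)) equals -sin(2pi/n (doy-t0)),
    # i.e. -wt.s; using that identity avoids recomputing a second sine.

    # ---------------- covariate window updates ---------------------------
    def _update_cov_windows(self, st, prefix, rng):
        ser = st[prefix]
        sig2 = ser.sig**2
        v0 = sig2 / (1.0 - ser.rho**2)
        mu_max, mu_min = self._mu_extrema(st)
        thx = st["th_max"]
        thn = st["th_min"]
        if prefix == "at":
            h_max, h_min = float(thx[1]), float(thn[1])  # d(mu)/d(max_cov or min_cov)
        else:
            h_max = float(thx[2])
            h_min = float(thn[2])
        smax2, smin2 = st["sigma_max"] ** 2, st["sigma_min"] ** 2
        g_max = st["mx"] - mu_max  # current Eq2 residuals
        g_min = st["mn"] - mu_min

        if self.m2:
            if prefix == "at":
                coefwt = np.full(self.T, st["delta"])
            else:
                coefwt = st["gamma"] * (-st["wt"].s)
            sz2 = st["sigma_zeta"] ** 2

        for name in ("a", "b"):
            d = np.ones(self.T) if name == "a" else ser.s
            for idxset in (self.even, self.odd):
                S2, S1 = _window_quad_stats(d, ser.eps, ser.rho, sig2, v0,
                                            self.ws, self.wid)
                phi = getattr(ser, name)
                prec = S2.copy()
                num = phi * S2 - S1
                if self.m2:
                    u = self._zeta_resid(st)
                    e = coefwt * d
                    Se2 = np.add.reduceat(e * e, self.ws) / sz2
                    Seu = np.add.reduceat(e * u, self.ws) / sz2
                    prec += Se2
                    num += phi * Se2 - Seu
                # extrema-regression coupling: mu_max/min depend on this window
                if prefix == "at":
                    ha1, ha2 = h_max, h_min  # d(mu_max)/d(a), d(mu_min)/d(a)
                    hb1, hb2 = h_max, -h_min
                else:  # mu_max uses min_q = a-b, mu_min uses max_q = a+b
                    ha1, ha2 = h_max, h_min
                    hb1, hb2 = -h_max, h_min
                if name == "a":
                    h1, h2 = ha1, ha2
                else:
                    h1, h2 = hb1, hb2
                # term g = (extremum - mu); d(g)/d(phi) = -h
                prec += h1 * h1 / smax2 + h2 * h2 / smin2
                num += phi * (h1 * h1 / smax2 + h2 * h2 / smin2)
                num += g_max * h1 / smax2 + g_min * h2 / smin2
                if name == "a":
                    prec_full = ser.tau0 + prec
                    mean = (ser.tau0 * ser.mu0 + num) / prec_full
                    new = mean + rng.standard_normal(self.W) / np.sqrt(prec_full)
                else:
                    prec_full = ser.tau_b + prec
                    mean = num / prec_full
                    new = _trunc_normal(rng, mean, 1.0 / np.sqrt(prec_full), lower=0.0)
                phi = phi.copy()
                phi[idxset] = new[idxset]
                setattr(ser, name, phi)
                ser.m = ser.a[self.wid] + ser.b[self.wid] * ser.s
                ser.eps = ser.x - ser.m
                mu_max, mu_min = self._mu_extrema(st)
                g_max = st["mx"] - mu_max
                g_min = st["mn"] - mu_min

    # ---------------- WT window updates ---------------------------------
    def _update_wt_windows_m2(self, st, rng):
        wt = st["wt"]
        sz2 = st["sigma_zeta"] ** 2
        mu_max, mu_min = self._mu_extrema(st)
        smax2, smin2 = st["sigma_max"] ** 2, st["sigma_min"] ** 2
        r = wt.x - st["delta"] * st["at"].eps
        if self.use_q:
            r -= st["gamma"] * (-wt.s) * st["q"].eps
        p = (1.0 + wt.s) / 2.0
        q = (1.0 - wt.s) / 2.0
        Sp2 = np.add.reduceat(p * p, self.ws)
        Sq2 = np.add.reduceat(q * q, self.ws)
        Spq = np.add.reduceat(p * q, self.ws)
        Spr = np.add.reduceat(p * r, self.ws)
        Sqr = np.add.reduceat(q * r, self.ws)
        # max | min
        prec = Sp2 / sz2 + 1.0 / smax2
        num = (Spr - Spq * st["mn"]) / sz2 + mu_max / smax2
        st["mx"] = _trunc_normal(rng, num / prec, 1.0 / np.sqrt(prec), lower=st["mn"])
        # min | max
        prec = Sq2 / sz2 + 1.0 / smin2
        num = (Sqr - Spq * st["mx"]) / sz2 + mu_min / smin2
        st["mn"] = _trunc_normal(rng, num / prec, 1.0 / np.sqrt(prec), upper=st["mx"])
        wt.m = self._wt_seasonal(st)
        wt.eps = wt.x - wt.m

    def _update_wt_windows_m1(self, st, rng):
        wt = st["wt"]
        sig2 = wt.sig**2
        v0 = sig2 / (1.0 - wt.rho**2)
        smax2, smin2 = st["sigma_max"] ** 2, st["sigma_min"] ** 2
        p = (1.0 + wt.s) / 2.0
        q = (1.0 - wt.s) / 2.0
        for name, d, sv, bound in (("mx", p, smax2, "lower"), ("mn", q, smin2, "upper")):
            mu_max, mu_min = self._mu_extrema(st)
            mu = mu_max if name == "mx" else mu_min
            for idxset in (self.even, self.odd):
                S2, S1 = _window_quad_stats(d, wt.eps, wt.rho, sig2, v0,
                                            self.ws, self.wid)
                phi = st[name]
                prec = S2 + 1.0 / sv
                num = phi * S2 - S1 + mu / sv
                mean = num / prec
                sd = 1.0 / np.sqrt(prec)
                if bound == "lower":
                    new = _trunc_normal(rng, mean, sd, lower=st["mn"])
                else:
                    new = _trunc_normal(rng, mean, sd, upper=st["mx"])
                phi = phi.copy()
                phi[idxset] = new[idxset]
                st[name] = phi
                wt.m = self._wt_seasonal(st)
                wt.eps = wt.x - wt.m

    # ---------------- theta / sigma updates ------------------------------
    def _update_theta(self, st, rng):
        X1 = self._theta_design(st)
        X2 = self._theta_design_min(st)
        smax2, smin2 = st["sigma_max"] ** 2, st["sigma_min"] ** 2
        k = X1.shape[1]
        if not self.cfg.share_intercept:
            P = X1.T @ X1 / smax2 + self.theta_tau * np.eye(k)
            b = X1.T @ st["mx"] / smax2
            st["th_max"] = _mvn_sample(rng, P, b)
            P = X2.T @ X2 / smin2 + self.theta_tau * np.eye(k)
            b = X2.T @ st["mn"] / smin2
            st["th_min"] = _mvn_sample(rng, P, b)
        else:
            # single shared intercept: joint draw of (th0, slopes_max, slopes_min)
            m = k - 1
            Z1 = np.zeros((self.W, 1 + 2 * m))
            Z1[:, 0] = 1.0
            Z1[:, 1:1 + m] = X1[:, 1:]
            Z2 = np.zeros((self.W, 1 + 2 * m))
            Z2[:, 0] = 1.0
            Z2[:, 1 + m:] = X2[:, 1:]
            P = Z1.T @ Z1 / smax2 + Z2.T @ Z2 / smin2 \
                + self.theta_tau * np.eye(1 + 2 * m)
            b = Z1.T @ st["mx"] / smax2 + Z2.T @ st["mn"] / smin2
            beta = _mvn_sample(rng, P, b)
            st["th_max"] = np.concatenate([[beta[0]], beta[1:1 + m]])
            st["th_min"] = np.concatenate([[beta[0]], beta[1 + m:]])

        mu_max, mu_min = self._mu_extrema(st)
        for key, resid, hn in (("sigma_max", st["mx"] - mu_max, self.hn_sigma_max),
                               ("sigma_min", st["mn"] - mu_min, self.hn_sigma_min)):
            ss = float(resid @ resid)
            n = len(resid)

            def logf(ls, ss=ss, n=n, hn=hn):
                s2 = math.exp(2.0 * ls)
                return -n * ls - 0.5 * ss / s2 - 0.5 * s2 / hn**2

            ls = _slice_sample(math.log(st[key]), logf, rng, w=0.4)
            st[key] = math.exp(ls)

    def _interweave_sigma_extrema(self, st, rng):
        """Non-centered (interweaved) update of the extrema-regression SDs.

        With few windows the centered Gibbs step suffers the classic funnel:
        once sigma_max is small the extrema stick to the regression surface
        and sigma_max cannot recover.  Re-expressing the extrema as
        ``mx = mu_max + sigma_max * eta`` with ``eta`` held fixed makes the
        daily water-temperature likelihood linear in sigma_max, giving a
        conjugate truncated-Normal update that restores mixing.
        """
        wt = st["wt"]
        p = (1.0 + wt.s) / 2.0
        q = (1.0 - wt.s) / 2.0
        for side in ("max", "min"):
            mu_max, mu_min = self._mu_extrema(st)
            if side == "max":
                mu, other, dsn, key, hn = mu_max, st["mn"], p, "sigma_max", self.hn_sigma_max
                other_dsn = q
                cur = st["mx"]
            else:
                mu, other, dsn, key, hn = mu_min, st["mx"], q, "sigma_min", self.hn_sigma_min
                other_dsn = p
                cur = st["mn"]
            sig = st[key]
            eta = (cur - mu) / sig
            dcol = eta[self.wid] * dsn
            base = mu[self.wid] * dsn + other[self.wid] * other_dsn
            if self.m2:
                r = wt.x - st["delta"] * st["at"].eps
                if self.use_q:
                    r = r - st["gamma"] * (-wt.s) * st["q"].eps
                resid0 = r - base
                sz2 = st["sigma_zeta"] ** 2
                prec = float(dcol @ dcol) / sz2 + 1.0 / hn**2
                num = float(dcol @ resid0) / sz2
            else:
                eps0 = wt.x - base
                rho, sw2 = wt.rho, wt.sig**2
                hd = dcol[1:] - rho * dcol[:-1]
                qd0 = eps0[1:] - rho * eps0[:-1]
                prec = (dcol[0] ** 2 * (1 - rho**2) + float(hd @ hd)) / sw2 \
                    + 1.0 / hn**2
                num = (dcol[0] * eps0[0] * (1 - rho**2) + float(hd @ qd0)) / sw2
            # the max >= min constraint is linear in sigma: per window it gives
            # a lower/upper bound depending on the sign of eta
            # max side: mu + sig*eta >= mn  <=>  sig*eta >= mn - mu
            # min side: mu + sig*eta <= mx  <=>  sig*eta <= mx - mu
            lo, hi = 0.0, np.inf
            pos, neg = eta > 0, eta < 0
            if side == "max":
                if pos.any():
                    lo = max(lo, float(np.max((other - mu)[pos] / eta[pos])))
                if neg.any():
                    hi = min(hi, float(np.min((other - mu)[neg] / eta[neg])))
            else:
                if pos.any():
                    hi = min(hi, float(np.min((other - mu)[pos] / eta[pos])))
                if neg.any():
                    lo = max(lo, float(np.max((other - mu)[neg] / eta[neg])))
            if not lo < hi:
                continue  # constraint leaves no room; keep the current value
            new_sig = float(_trunc_normal(rng, num / prec, 1.0 / math.sqrt(prec),
                                          lower=max(lo, 1e-10), upper=hi))
            if not np.isfinite(new_sig) or new_sig <= 0:
                continue
            st[key] = new_sig
            if side == "max":
                st["mx"] = mu + new_sig * eta
            else:
                st["mn"] = mu + new_sig * eta
        wt.m = self._wt_seasonal(st)
        wt.eps = wt.x - wt.m

    def _update_link(self, st, rng):
        wt = st["wt"]
        u0 = wt.eps  # x - seasonal
        f1 = st["at"].eps
        if self.use_q:
            f2 = (-wt.s) * st["q"].eps
            F = np.column_stack([f1, f2])
        else:
            F = f1[:, None]
        sz2 = st["sigma_zeta"] ** 2
        P = F.T @ F / sz2 + self.link_tau * np.eye(F.shape[1])
        b = F.T @ u0 / sz2
        coef = _mvn_sample(rng, P, b)
        st["delta"] = float(coef[0])
        if self.use_q:
            st["gamma"] = float(coef[1])
        resid = u0 - F @ coef
        ss = float(resid @ resid)
        n = len(resid)
        hn = self.hn_sigma_zeta

        def logf(ls):
            s2 = math.exp(2.0 * ls)
            return -n * ls - 0.5 * ss / s2 - 0.5 * s2 / hn**2

        st["sigma_zeta"] = math.exp(
            _slice_sample(math.log(st["sigma_zeta"]), logf, rng, w=0.2)
        )

    # ---------------- AR(1) parameter updates ----------------------------
    @staticmethod
    def _ar1_suffstats(eps):
        e0 = float(eps[0])
        s00 = float(eps[1:] @ eps[1:])
        s01 = float(eps[1:] @ eps[:-1])
        s11 = float(eps[:-1] @ eps[:-1])
        return e0, s00, s01, s11, len(eps)

    def _update_ar1(self, st, ser, rng, hn_sig, rho_bounds):
        e0, s00, s01, s11, n = self._ar1_suffstats(ser.eps)
        sig = ser.sig

        def logf_rho(r):
            if not (-1.0 < r < 1.0):
                return -np.inf
            ss = s00 - 2.0 * r * s01 + r * r * s11
            return 0.5 * math.log1p(-r * r) \
                - 0.5 * (e0 * e0 * (1.0 - r * r) + ss) / sig**2

        lo = max(rho_bounds[0], -1.0 + 1e-9)
        hi = min(rho_bounds[1], 1.0 - 1e-9)
        ser.rho = float(np.clip(
            _slice_sample(ser.rho, logf_rho, rng, w=0.1, lower=lo, upper=hi), lo, hi))

        r = ser.rho
        ss = s00 - 2.0 * r * s01 + r * r * s11 + e0 * e0 * (1.0 - r * r)

        def logf_sig(ls):
            s2 = math.exp(2.0 * ls)
            return -n * ls - 0.5 * ss / s2 - 0.5 * s2 / hn_sig**2

        ser.sig = math.exp(_slice_sample(math.log(ser.sig), logf_sig, rng, w=0.2))

    # ---------------- phase updates --------------------------------------
    #
    # The phase t0 rides a long ridge with the window means/amplitudes: a
    # small phase shift can be largely compensated by adjusting every
    # (alpha_y, beta_y).  A plain random walk on t0 alone therefore diffuses
    # very slowly.  Instead, each proposal translates the window parameters
    # by the shift of their per-window least-squares fit between the two
    # phases, g(t0') - g(t0).  The map is a state-independent translation
    # (Jacobian one), so standard Metropolis acceptance on the joint density
    # applies, and moves travel along the ridge instead of across it.

    def _ls_map(self, x, s, ridge=1e-3):
        """Per-window least-squares (mean, amplitude) fit of ``x`` on ``s``."""
        ones = np.ones(self.T)
        S1 = np.add.reduceat(ones, self.ws) + ridge
        Ss = np.add.reduceat(s, self.ws)
        Ss2 = np.add.reduceat(s * s, self.ws) + ridge
        Sx = np.add.reduceat(x, self.ws)
        Sxs = np.add.reduceat(x * s, self.ws)
        det = S1 * Ss2 - Ss * Ss
        a = (Ss2 * Sx - Ss * Sxs) / det
        b = (S1 * Sxs - Ss * Sx) / det
        return a, b

    def _cov_t0_target(self, st, prefix, t0, a, b):
        """Joint-density terms involving (t0, a, b) of one covariate series.

        Residuals at the series' missing days are held fixed under the move
        (the latent values translate with the seasonal surface), so imputed
        data cannot anchor the phase.
        """
        ser = st[prefix]
        if np.any(b < 0):
            return -np.inf, None, None
        s = np.sin(2.0 * np.pi / self.nyr * (self.doy - t0))
        eps = ser.x - a[self.wid] - b[self.wid] * s
        if ser.miss.size:
            eps[ser.miss] = ser.eps[ser.miss]
        r, sig2 = ser.rho, ser.sig**2
        qd = eps[1:] - r * eps[:-1]
        ll = -0.5 * (eps[0] ** 2 * (1.0 - r * r) + float(qd @ qd)) / sig2
        if self.m2:
            wt = st["wt"]
            if prefix == "at":
                u = wt.x - wt.m - st["delta"] * eps
                if self.use_q:
                    u = u - st["gamma"] * (-wt.s) * st["q"].eps
            else:
                u = wt.x - wt.m - st["delta"] * st["at"].eps \
                    - st["gamma"] * (-wt.s) * eps
            ll += -0.5 * float(u @ u) / st["sigma_zeta"] ** 2
        # extrema-regression terms with this series' extrema replaced
        thx, thn = st["th_max"], st["th_min"]
        at, q = st["at"], (st["q"] if self.use_q else None)
        max_at = (a + b) if prefix == "at" else (at.a + at.b)
        min_at = (a - b) if prefix == "at" else (at.a - at.b)
        mu_max = thx[0] + thx[1] * max_at
        mu_min = thn[0] + thn[1] * min_at
        if self.use_q:
            min_q = (a - b) if prefix == "q" else (q.a - q.b)
            max_q = (a + b) if prefix == "q" else (q.a + q.b)
            mu_max = mu_max + thx[2] * min_q
            mu_min = mu_min + thn[2] * max_q
        ll += -0.5 * float(((st["mx"] - mu_max) ** 2).sum()) / st["sigma_max"] ** 2
        ll += -0.5 * float(((st["mn"] - mu_min) ** 2).sum()) / st["sigma_min"] ** 2
        ll += -0.5 * ser.tau0 * float(((a - ser.mu0) ** 2).sum())
        ll += -0.5 * ser.tau_b * float((b**2).sum())
        return float(ll), s, eps

    def _update_cov_t0(self, st, prefix, rng, adapting):
        ser = st[prefix]
        n = float(self.nyr.max())
        prop = (ser.t0 + ser.mh_scale * rng.standard_normal()) % n
        accept = False
        if ser.t0_lo <= prop < min(ser.t0_hi, n):
            a0_map, b0_map = self._ls_map(ser.x, ser.s)
            s1 = np.sin(2.0 * np.pi / self.nyr * (self.doy - prop))
            a1_map, b1_map = self._ls_map(ser.x, s1)
            a_new = ser.a + (a1_map - a0_map)
            b_new = ser.b + (b1_map - b0_map)
            ll0, _, _ = self._cov_t0_target(st, prefix, ser.t0, ser.a, ser.b)
            ll1, s_new, eps_new = self._cov_t0_target(st, prefix, prop, a_new, b_new)
            accept = np.isfinite(ll1) and math.log(rng.uniform()) < ll1 - ll0
            if accept:
                ser.t0 = prop
                ser.a, ser.b = a_new, b_new
                ser.s = s_new
                ser.m = ser.a[self.wid] + ser.b[self.wid] * ser.s
                ser.eps = eps_new
                if ser.miss.size:  # latent values ride along with the surface
                    ser.x[ser.miss] = ser.m[ser.miss] + eps_new[ser.miss]
        ser.mh_n += 1
        ser.mh_acc += int(accept)
        if adapting and ser.mh_n % 50 == 0:
            rate = ser.mh_acc / 50.0
            ser.mh_scale *= math.exp((rate - 0.44) * 1.0)
            ser.mh_scale = float(np.clip(ser.mh_scale, 0.05, 60.0))
            ser.mh_acc = 0

    def _wt_t0_target(self, st, t0, mx, mn):
        """Joint-density terms for a WT phase move; the white-noise (M2) or
        AR(1) (M1) residuals at missing WT days are held fixed so latent
        values ride along with the seasonal surface."""
        if np.any(mx < mn):
            return -np.inf, None, None, None
        wt = st["wt"]
        miss = self.wt_miss_idx
        s = np.sin(2.0 * np.pi / self.nyr * (self.doy - t0))
        a = (mx + mn) / 2.0
        b = (mx - mn) / 2.0
        m = a[self.wid] + b[self.wid] * s
        eps = wt.x - m
        if self.m2:
            link = st["delta"] * st["at"].eps
            if self.use_q:
                link = link + st["gamma"] * (-s) * st["q"].eps
            u = eps - link
            if miss.size:
                link_old = st["delta"] * st["at"].eps
                if self.use_q:
                    link_old = link_old + st["gamma"] * (-wt.s) * st["q"].eps
                u_old = wt.eps - link_old
                u[miss] = u_old[miss]
                eps[miss] = link[miss] + u_old[miss]
            ll = -0.5 * float(u @ u) / st["sigma_zeta"] ** 2
        else:
            if miss.size:
                eps[miss] = wt.eps[miss]
            r, sig2 = wt.rho, wt.sig**2
            qd = eps[1:] - r * eps[:-1]
            ll = -0.5 * (eps[0] ** 2 * (1.0 - r * r) + float(qd @ qd)) / sig2
        mu_max, mu_min = self._mu_extrema(st)
        ll += -0.5 * float(((mx - mu_max) ** 2).sum()) / st["sigma_max"] ** 2
        ll += -0.5 * float(((mn - mu_min) ** 2).sum()) / st["sigma_min"] ** 2
        return float(ll), s, m, eps

    def _wt_pseudo_data(self, st, s):
        """Daily WT minus the covariate-link mean at phase s (M2) or raw WT."""
        wt = st["wt"]
        if not self.m2:
            return wt.x
        r = wt.x - st["delta"] * st["at"].eps
        if self.use_q:
            r = r - st["gamma"] * (-s) * st["q"].eps
        return r

    def _update_wt_t0(self, st, rng, adapting):
        wt = st["wt"]
        scale, acc, cnt = st["wt_mh"]
        n = float(self.nyr.max())
        prop = (wt.t0 + scale * rng.standard_normal()) % n
        lo, hi = self.t0_wt_bounds
        accept = False
        if lo <= prop < min(hi, n):
            s1 = np.sin(2.0 * np.pi / self.nyr * (self.doy - prop))
            a0_map, b0_map = self._ls_map(self._wt_pseudo_data(st, wt.s), wt.s)
            a1_map, b1_map = self._ls_map(self._wt_pseudo_data(st, s1), s1)
            # translate in extrema space: max = a + b, min = a - b
            mx_new = st["mx"] + (a1_map + b1_map) - (a0_map + b0_map)
            mn_new = st["mn"] + (a1_map - b1_map) - (a0_map - b0_map)
            ll0, *_ = self._wt_t0_target(st, wt.t0, st["mx"], st["mn"])
            ll1, s_new, m_new, eps_new = self._wt_t0_target(st, prop, mx_new, mn_new)
            accept = np.isfinite(ll1) and math.log(rng.uniform()) < ll1 - ll0
            if accept:
                wt.t0 = prop
                st["mx"], st["mn"] = mx_new, mn_new
                wt.s, wt.m, wt.eps = s_new, m_new, eps_new
                if self.wt_miss_idx.size:
                    wt.x[self.wt_miss_idx] = (m_new + eps_new)[self.wt_miss_idx]
        cnt += 1
        acc += int(accept)
        if adapting and cnt % 50 == 0:
            scale *= math.exp((acc / 50.0 - 0.44) * 1.0)
            scale = float(np.clip(scale, 0.05, 60.0))
            acc = 0
        st["wt_mh"] = [scale, acc, cnt]

    def _update_joint_phase(self, st, rng, adapting):
        """Common phase shift of all series, window blocks translated along.

        The link between daily WT and AT deviations ties the individual
        phases together: shifting one alone is heavily penalised, so the
        slow posterior direction is the common shift.  This move proposes
        one offset for every t0 simultaneously, translating each series'
        window parameters (and, through the held residuals, its latent
        values) with the same least-squares maps as the single-series moves;
        the composite map is a shear with unit Jacobian.
        """
        scale, acc, cnt = st["joint_mh"]
        n = float(self.nyr.max())
        dlt = scale * rng.standard_normal()
        wt = st["wt"]
        ok = True
        prop = {}
        ll0 = 0.0
        ll1 = 0.0
        for prefix in ("at", "q") if self.use_q else ("at",):
            ser = st[prefix]
            t1 = (ser.t0 + dlt) % n
            if not (ser.t0_lo <= t1 < min(ser.t0_hi, n)):
                ok = False
                break
            a0m, b0m = self._ls_map(ser.x, ser.s)
            s1 = np.sin(2.0 * np.pi / self.nyr * (self.doy - t1))
            a1m, b1m = self._ls_map(ser.x, s1)
            a_new = ser.a + (a1m - a0m)
            b_new = ser.b + (b1m - b0m)
            if np.any(b_new < 0):
                ok = False
                break
            eps_new = ser.x - a_new[self.wid] - b_new[self.wid] * s1
            if ser.miss.size:
                eps_new[ser.miss] = ser.eps[ser.miss]
            # AR1 terms + alpha/beta priors, old and new
            for (eps_k, a_k, b_k, llk) in ((ser.eps, ser.a, ser.b, 0),
                                           (eps_new, a_new, b_new, 1)):
                r, sig2 = ser.rho, ser.sig**2
                qd = eps_k[1:] - r * eps_k[:-1]
                v = -0.5 * (eps_k[0] ** 2 * (1 - r * r) + float(qd @ qd)) / sig2
                v += -0.5 * ser.tau0 * float(((a_k - ser.mu0) ** 2).sum())
                v += -0.5 * ser.tau_b * float((b_k**2).sum())
                if llk:
                    ll1 += v
                else:
                    ll0 += v
            prop[prefix] = (t1, a_new, b_new, s1, eps_new)
        t1w = (wt.t0 + dlt) % n
        lo, hi = self.t0_wt_bounds
        if ok and lo <= t1w < min(hi, n):
            eps_at1 = prop["at"][4]
            eps_q1 = prop["q"][4] if self.use_q else None
            s1w = np.sin(2.0 * np.pi / self.nyr * (self.doy - t1w))
            if self.m2:
                link0 = st["delta"] * st["at"].eps
                link1 = st["delta"] * eps_at1
                if self.use_q:
                    link0 = link0 + st["gamma"] * (-wt.s) * st["q"].eps
                    link1 = link1 + st["gamma"] * (-s1w) * eps_q1
                r0 = wt.x - link0
                r1 = wt.x - link1
            else:
                r0 = r1 = wt.x
            a0m, b0m = self._ls_map(r0, wt.s)
            a1m, b1m = self._ls_map(r1, s1w)
            mx1 = st["mx"] + (a1m + b1m) - (a0m + b0m)
            mn1 = st["mn"] + (a1m - b1m) - (a0m - b0m)
            if np.any(mx1 < mn1):
                ok = False
            else:
                a_w = (mx1 + mn1) / 2.0
                b_w = (mx1 - mn1) / 2.0
                m1 = a_w[self.wid] + b_w[self.wid] * s1w
                eps_w1 = wt.x - m1
                miss = self.wt_miss_idx
                if self.m2:
                    u1 = eps_w1 - link1
                    if miss.size:
                        u0 = wt.eps - link0
                        u1[miss] = u0[miss]
                        eps_w1[miss] = link1[miss] + u0[miss]
                        u0_full = u0
                    else:
                        u0_full = wt.eps - link0
                    ll0 += -0.5 * float(u0_full @ u0_full) / st["sigma_zeta"] ** 2
                    ll1 += -0.5 * float(u1 @ u1) / st["sigma_zeta"] ** 2
                else:
                    if miss.size:
                        eps_w1[miss] = wt.eps[miss]
                    r_, sg2 = wt.rho, wt.sig**2
                    for eps_k, llk in ((wt.eps, 0), (eps_w1, 1)):
                        qd = eps_k[1:] - r_ * eps_k[:-1]
                        v = -0.5 * (eps_k[0] ** 2 * (1 - r_ * r_)
                                    + float(qd @ qd)) / sg2
                        if llk:
                            ll1 += v
                        else:
                            ll0 += v
                # extrema regression at old/new window values
                def eq2(mx_k, mn_k, at_a, at_b, q_ab):
                    thx, thn = st["th_max"], st["th_min"]
                    mu_max = thx[0] + thx[1] * (at_a + at_b)
                    mu_min = thn[0] + thn[1] * (at_a - at_b)
                    if self.use_q:
                        qa, qb = q_ab
                        mu_max = mu_max + thx[2] * (qa - qb)
                        mu_min = mu_min + thn[2] * (qa + qb)
                    return (-0.5 * float(((mx_k - mu_max) ** 2).sum())
                            / st["sigma_max"] ** 2
                            - 0.5 * float(((mn_k - mu_min) ** 2).sum())
                            / st["sigma_min"] ** 2)

                q_old = (st["q"].a, st["q"].b) if self.use_q else None
                q_new = (prop["q"][1], prop["q"][2]) if self.use_q else None
                ll0 += eq2(st["mx"], st["mn"], st["at"].a, st["at"].b, q_old)
                ll1 += eq2(mx1, mn1, prop["at"][1], prop["at"][2], q_new)
        else:
            ok = False

        accept = ok and math.log(rng.uniform()) < ll1 - ll0
        if accept:
            for prefix, (t1, a_new, b_new, s1, eps_new) in prop.items():
                ser = st[prefix]
                ser.t0, ser.a, ser.b, ser.s = t1, a_new, b_new, s1
                ser.m = ser.a[self.wid] + ser.b[self.wid] * ser.s
                ser.eps = eps_new
                if ser.miss.size:
                    ser.x[ser.miss] = ser.m[ser.miss] + eps_new[ser.miss]
            wt.t0 = t1w
            st["mx"], st["mn"] = mx1, mn1
            wt.s, wt.m, wt.eps = s1w, m1, eps_w1
            if self.wt_miss_idx.size:
                wt.x[self.wt_miss_idx] = (m1 + eps_w1)[self.wt_miss_idx]
        cnt += 1
        acc += int(accept)
        if adapting and cnt % 50 == 0:
            scale *= math.exp((acc / 50.0 - 0.35) * 1.0)
            scale = float(np.clip(scale, 0.05, 45.0))
            acc = 0
        st["joint_mh"] = [scale, acc, cnt]

    # ---------------- imputation -----------------------------------------
    def _impute_wt(self, st, rng):
        idx = self.wt_miss_idx
        if idx.size == 0:
            return
        wt = st["wt"]
        if self.m2:
            mean = wt.m[idx] + st["delta"] * st["at"].eps[idx]
            if self.use_q:
                mean += st["gamma"] * (-wt.s[idx]) * st["q"].eps[idx]
            wt.x[idx] = mean + st["sigma_zeta"] * rng.standard_normal(idx.size)
            wt.eps = wt.x - wt.m
        else:
            self._impute_ar1_checkerboard(wt, idx, rng)

    def _impute_ar1_checkerboard(self, ser, idx, rng, extra_prec=None, extra_num=None):
        """Refresh latent residuals at ``idx`` from the AR(1) full conditional.

        ``extra_prec``/``extra_num`` (per missing day) add the Gaussian
        information flowing back from the daily WT equation (M2 covariates).
        """
        r, sig2 = ser.rho, ser.sig**2
        T = self.T
        for parity in (0, 1):
            sub = idx[idx % 2 == parity]
            if sub.size == 0:
                continue
            eps = ser.eps
            interior = (sub > 0) & (sub < T - 1)
            prec = np.empty(sub.size)
            num = np.empty(sub.size)
            em1 = eps[np.clip(sub - 1, 0, T - 1)]
            ep1 = eps[np.clip(sub + 1, 0, T - 1)]
            prec[:] = (1.0 + r * r) / sig2
            num[:] = r * (em1 + ep1) / sig2
            edge_lo = sub == 0
            edge_hi = sub == T - 1
            prec[edge_lo] = 1.0 / sig2
            num[edge_lo] = r * ep1[edge_lo] / sig2
            prec[edge_hi] = 1.0 / sig2
            num[edge_hi] = r * em1[edge_hi] / sig2
            if extra_prec is not None:
                sel = idx % 2 == parity
                prec += extra_prec[sel]
                num += extra_num[sel]
            mean = num / prec
            draw = mean + rng.standard_normal(sub.size) / np.sqrt(prec)
            ser.eps[sub] = draw
            ser.x[sub] = ser.m[sub] + draw

    def _impute_covariate(self, st, prefix, rng):
        ser = st[prefix]
        idx = ser.miss
        if idx.size == 0:
            return
        if self.m2:
            wt = st["wt"]
            if prefix == "at":
                c = np.full(idx.size, st["delta"])
                other = 0.0
                if self.use_q:
                    other = st["gamma"] * (-wt.s[idx]) * st["q"].eps[idx]
                wres = wt.x[idx] - wt.m[idx] - other
            else:
                c = st["gamma"] * (-wt.s[idx])
                wres = wt.x[idx] - wt.m[idx] - st["delta"] * st["at"].eps[idx]
            sz2 = st["sigma_zeta"] ** 2
            extra_prec = c * c / sz2
            extra_num = c * wres / sz2
        else:
            extra_prec = extra_num = None
        self._impute_ar1_checkerboard(ser, idx, rng,
                                      extra_prec=extra_prec, extra_num=extra_num)

    # ---------------- one sweep ------------------------------------------
    def sweep(self, st, rng, adapting: bool):
        self._update_cov_windows(st, "at", rng)
        if self.use_q:
            self._update_cov_windows(st, "q", rng)
        self._update_cov_t0(st, "at", rng, adapting)
        if self.use_q:
            self._update_cov_t0(st, "q", rng, adapting)
        self._update_ar1(st, st["at"], rng, st["at"].hn_sig,
                         (st["at"].rho_lo, st["at"].rho_hi))
        if self.use_q:
            self._update_ar1(st, st["q"], rng, st["q"].hn_sig,
                             (st["q"].rho_lo, st["q"].rho_hi))
        if self.m2:
            self._update_wt_windows_m2(st, rng)
        else:
            self._update_wt_windows_m1(st, rng)
        self._update_wt_t0(st, rng, adapting)
        self._update_joint_phase(st, rng, adapting)
        self._update_theta(st, rng)
        self._interweave_sigma_extrema(st, rng)
        if self.m2:
            self._update_link(st, rng)
        else:
            self._update_ar1(st, st["wt"], rng, self.hn_sigma_wt, self.rho_wt_bounds)
        self._impute_wt(st, rng)
        self._impute_covariate(st, "at", rng)
        if self.use_q:
            self._impute_covariate(st, "q", rng)

    # ---------------- recording ------------------------------------------
    def monitored(self, st) -> dict:
        wt = st["wt"]
        out = {
            "t0_at": st["at"].t0, "rho_at": st["at"].rho, "sigma_at": st["at"].sig,
            "t0_wt": wt.t0,
            "alpha_at": st["at"].a.copy(), "beta_at": st["at"].b.copy(),
            "max_wt": st["mx"].copy(), "min_wt": st["mn"].copy(),
            "alpha_wt": (st["mx"] + st["mn"]) / 2.0,
            "beta_wt": (st["mx"] - st["mn"]) / 2.0,
            "theta0": st["th_max"][0], "theta1": st["th_max"][1],
            "theta0p": st["th_min"][0], "theta1p": st["th_min"][1],
            "sigma_max": st["sigma_max"], "sigma_min": st["sigma_min"],
        }
        if self.use_q:
            out.update({
                "t0_q": st["q"].t0, "rho_q": st["q"].rho, "sigma_q": st["q"].sig,
                "alpha_q": st["q"].a.copy(), "beta_q": st["q"].b.copy(),
                "theta2": st["th_max"][2], "theta2p": st["th_min"][2],
            })
        if self.m2:
            out.update({"delta": st["delta"], "sigma_zeta": st["sigma_zeta"]})
            if self.use_q:
                out["gamma"] = st["gamma"]
        else:
            out.update({"rho_wt": wt.rho, "sigma_wt": wt.sig})
        if self.mcmc.keep_latent:
            if self.wt_miss_idx.size:
                out["wt_imp"] = st["wt"].x[self.wt_miss_idx].copy()
            if self.at_miss_idx.size:
                out["at_imp"] = st["at"].x[self.at_miss_idx].copy()
            if self.use_q and self.q_miss_idx.size:
                out["q_imp"] = st["q"].x[self.q_miss_idx].copy()
        return out

    def log_joint(self, st) -> float:
        """Joint log posterior at the current state (via the core assembly)."""
        state = self.export_state(st)
        data = {"WT": DailySeries(self.windows.dates, self.wt_vals, self.wt_obs, "WT"),
                "AT": DailySeries(self.windows.dates, self.at_vals, self.at_obs, "AT")}
        if self.use_q:
            data["LOGQ"] = DailySeries(self.windows.dates, self.q_vals, self.q_obs, "LOGQ")
        return joint_logposterior(data, self.windows, state, self.cfg, self.priors)

    def export_state(self, st) -> ModelState:
        n = int(self.nyr.max())
        at = st["at"]
        kw = dict(
            at_seasonal=SeasonalParams(at.a, at.b, at.t0, n),
            at_ar1=AR1Params(at.rho, at.sig),
            wt_extrema=ExtremaParams(st["mx"], st["mn"]),
            wt_t0=st["wt"].t0,
            theta=ThetaParams(
                st["th_max"][0], st["th_max"][1], st["th_min"][0], st["th_min"][1],
                st["th_max"][2] if self.use_q else 0.0,
                st["th_min"][2] if self.use_q else 0.0,
                st["sigma_max"], st["sigma_min"],
            ),
            wt_missing=st["wt"].x[self.wt_miss_idx].copy(),
            at_missing=at.x[self.at_miss_idx].copy(),
        )
        if self.use_q:
            q = st["q"]
            kw.update(q_seasonal=SeasonalParams(q.a, q.b, q.t0, n),
                      q_ar1=AR1Params(q.rho, q.sig),
                      q_missing=q.x[self.q_miss_idx].copy())
        if self.m2:
            kw["link"] = ShortTermLinkParams(
                st["delta"], st["gamma"] if self.use_q else 0.0, st["sigma_zeta"])
        else:
            kw["wt_ar1"] = AR1Params(st["wt"].rho, st["wt"].sig)
        return ModelState(**kw)


# ---------------------------------------------------------------------------
# public driver
# ---------------------------------------------------------------------------


def _validate_overlap(data, windows, use_q) -> None:
    wt_obs = data["WT"].observed_mask
    cov_obs = data["AT"].observed_mask.copy()
    if use_q:
        cov_obs = cov_obs | data["LOGQ"].observed_mask
    full = ~windows.is_partial
    n_overlap = 0
    for y in range(windows.n_windows):
        if not full[y]:
            continue
        sl = slice(windows.starts[y], windows.stops[y])
        if wt_obs[sl].sum() >= 10 and cov_obs[sl].sum() >= 10:
            n_overlap += 1
    if n_overlap < 2:
        raise ValueError(
            "water temperature must overlap the covariates on at least two "
            f"full half-year windows (found {n_overlap})"
        )


def fit(
    data: Mapping[str, DailySeries],
    priors: Optional[PriorSpec] = None,
    mcmc: Optional[McmcConfig] = None,
    check_convergence: bool = True,
) -> Tuple[PosteriorDraws, Optional[ConvergenceReport]]:
    """Fit the model by MCMC and return labelled posterior draws.

    All series must share one gap-free daily calendar (missing values flagged
    in the mask); latent values at unobserved days are sampled jointly with
    the parameters.  Deterministic given ``mcmc.seed``.
    """
    mcmc = mcmc or McmcConfig()
    kinds = {"WT", "AT"} | ({"LOGQ"} if mcmc.use_discharge else set())
    for kind in kinds:
        if kind not in data:
            raise ValueError(f"missing required series {kind}")
    ref = data["WT"].dates
    for kind in kinds:
        if len(data[kind].dates) != len(ref) or not np.array_equal(data[kind].dates, ref):
            raise ValueError("all series must cover the same calendar days")
    if data["WT"].n_observed == 0:
        raise ValueError("water-temperature series has no observed days")
    windows = build_windows(ref)
    _validate_overlap(data, windows, mcmc.use_discharge)

    if priors is None:
        priors = default_priors(data, windows, mcmc.model_config)

    sampler = _Gibbs(data, windows, priors, mcmc)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    n_sweeps = mcmc.n_burnin + mcmc.n_keep * mcmc.thin

    chain_records: list = []
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[c])
        st = sampler.init_state(rng, jitter=1.0 if c else 0.25)
        lj = sampler.log_joint(st)
        if not np.isfinite(lj):
            raise RuntimeError(
                f"non-finite log posterior at initialisation of chain {c}"
            )
        records: Dict[str, list] = {}
        kept = 0
        for i in range(n_sweeps):
            sampler.sweep(st, rng, adapting=i < mcmc.n_burnin)
            if i >= mcmc.n_burnin and (i - mcmc.n_burnin) % mcmc.thin == 0:
                mon = sampler.monitored(st)
                if not records:
                    records = {nm: np.empty((mcmc.n_keep,) + np.shape(v))
                               for nm, v in mon.items()}
                for nm, v in mon.items():
                    records[nm][kept] = v
                kept += 1
        chain_records.append(records)
        logger.info("chain %d/%d finished (%d sweeps)", c + 1, mcmc.n_chains, n_sweeps)

    arrays = {nm: np.stack([rec[nm] for rec in chain_records])
              for nm in chain_records[0]}
    date_str = pd.DatetimeIndex(ref).strftime("%Y-%m-%d").to_numpy()
    labels = {}
    for nm in arrays:
        if arrays[nm].ndim == 3:
            if nm.endswith("_imp"):
                idx = {"wt_imp": sampler.wt_miss_idx, "at_imp": sampler.at_miss_idx,
                       "q_imp": sampler.q_miss_idx}[nm]
                labels[nm] = list(date_str[idx])
            else:
                labels[nm] = list(range(arrays[nm].shape[2]))
    meta = {
        "windows": windows,
        "data": dict(data),
        "mcmc": mcmc,
        "config": mcmc.model_config,
        "priors": priors,
        "missing_idx": {"WT": sampler.wt_miss_idx, "AT": sampler.at_miss_idx,
                        "LOGQ": sampler.q_miss_idx},
    }
    draws = PosteriorDraws(arrays, labels, meta)
    report = _convergence_report(draws) if check_convergence else None
    if report is not None and not report.all_ok:
        bad = report.failures()
        logger.warning("%d parameters failed convergence checks (worst rhat %.3f)",
                       len(bad), float(np.nanmax(bad["rhat"])) if len(bad) else np.nan)
    return draws, report
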