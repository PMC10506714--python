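"""Prior specifications for the hierarchical fit.

The sampler exploits conjugacy, so each parameter class is tied to a prior
family (hyperparameters are free, the family is not):

====================  =========================  =========================
parameter             family                     default
====================  =========================  =========================
theta*, delta, gamma  normal                     Normal(0, 10)
rho (all series)      uniform                    Uniform(-1, 1)
sigma (all)           halfnormal                 HalfNormal(2 x empirical
                                                 residual SD)
alpha_y (covariates)  normal                     Normal(empirical window
                                                 mean, 10)
beta_y  (covariates)  halfnormal                 HalfNormal(10)
t0 (all series)       uniform                    Uniform(0, n)
====================  =========================  =========================

Water-temperature window extrema take their prior from the extrema
regression itself (the hierarchical link), so they carry no entry here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import DailySeries, ModelConfig, WindowIndex

__all__ = ["Prior", "PriorSpec", "default_priors"]

_HALFNORM_CONST = 0.5 * math.log(2.0 / math.pi)
_NORM_CONST = -0.5 * math.log(2.0 * math.pi)


@dataclass
class Prior:
    """One univariate prior; ``loc``/``scale`` may be vectors for per-window blocks."""

    family: str  # "normal" | "halfnormal" | "uniform"
    loc: np.ndarray = 0.0  # normal mean / uniform lower bound
    scale: np.ndarray = 1.0  # normal or halfnormal SD / uniform upper bound

    def __post_init__(self) -> None:
        if self.family not in ("normal", "halfnormal", "uniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        self.loc = np.asarray(self.loc, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.family == "uniform":
            if np.any(self.scale <= self.loc):
                raise ValueError("uniform prior needs upper > lower")
        elif np.any(self.scale <= 0):
            raise ValueError("prior scale must be positive")

    @property
    def lower(self) -> float:
        if self.family == "uniform":
            return float(np.min(self.loc))
        if self.family == "halfnormal":
            return 0.0
        return -np.inf

    @property
    def upper(self) -> float:
        if self.family == "uniform":
            return float(np.max(self.scale))
        return np.inf

    def logpdf(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if self.family == "normal":
            z = (x - self.loc) / self.scale
            return float(np.sum(_NORM_CONST - np.log(self.scale) - 0.5 * z * z))
        if self.family == "halfnormal":
            if np.any(x < 0):
                return -np.inf
            z = x / self.scale
            return float(np.sum(_NORM_CONST + math.log(2.0) - np.log(self.scale) - 0.5 * z * z))
        lo, hi = self.loc, self.scale
        if np.any(x < lo) or np.any(x > hi):
            return -np.inf
        return float(-np.sum(np.log(hi - lo)))


def _empirical_sine_stats(series: DailySeries, windows: WindowIndex):
    """Crude per-window LS sine fit used only to scale the default priors.

    Returns (per-window means, best phase, residual SD, per-window amplitudes).
    """
    obs = series.observed_mask
    x = series.values
    best = None
    doy, n = windows.day_of_year, windows.n_per_year
    wid = windows.window_id
    W = windows.n_windows
    for t0 in np.arange(0.0, 365.0, 7.0):
        s = np.sin(2.0 * np.pi / n * (doy - t0))
        alpha = np.zeros(W)
        beta = np.zeros(W)
        sse = 0.0
        for y in range(W):
            sel = obs & (wid == y)
            if sel.sum() < 4:
                alpha[y] = np.nanmean(np.where(obs, x, np.nan))
                continue
            A = np.column_stack([np.ones(sel.sum()), s[sel]])
            coef, res, *_ = np.linalg.lstsq(A, x[sel], rcond=None)
            alpha[y], beta[y] = coef
            r = x[sel] - A @ coef
            sse += float(r @ r)
        if best is None or sse < best[0]:
            best = (sse, t0, alpha.copy(), beta.copy())
    sse, t0, alpha, beta = best
    nobs = max(int(obs.sum()), 1)
    resid_sd = max(math.sqrt(sse / nobs), 1e-3)
    # fold any negative amplitudes into the phase convention
    if np.median(beta) < 0:
        beta = -beta
        t0 = (t0 + 365.0 / 2.0) % 365.0
    beta = np.abs(beta)
    return alpha, float(t0), resid_sd, beta


# which prior family each parameter class must keep (conjugacy / support)
_FAMILY_RULES = {
    "theta": ("normal",),
    "delta": ("normal",),
    "gamma": ("normal",),
    "rho": ("uniform",),
    "sigma": ("halfnormal",),
    "alpha": ("normal",),
    "beta": ("halfnormal",),
    "t0": ("uniform",),
}


def _rule_for(name: str) -> tuple:
    if name.startswith("theta"):
        return "theta", _FAMILY_RULES["theta"]
    for key in ("rho", "sigma", "alpha", "beta", "t0", "delta", "gamma"):
        if name == key or name.startswith(key + "_"):
            return key, _FAMILY_RULES[key]
    raise KeyError(f"unknown parameter {name!r}")


class PriorSpec(Mapping):
    """Mapping of parameter name -> :class:`Prior` with family/support validation.

    Keys follow the sampler's naming: ``theta0 theta1 theta2 theta0p theta1p
    theta2p sigma_max sigma_min delta gamma sigma_zeta rho_at sigma_at rho_q
    sigma_q rho_wt sigma_wt t0_at t0_q t0_wt alpha_at beta_at alpha_q beta_q``
    (the last four are per-window vectors).
    """

    def __init__(self, priors: dict):
        self._priors = dict(priors)
        for name, prior in self._priors.items():
            self._validate(name, prior)

    @staticmethod
    def _validate(name: str, prior: Prior) -> None:
        key, families = _rule_for(name)
        if prior.family not in families:
            raise ValueError(
                f"prior for {name!r} must be of family {families} "
                f"(conjugate sampler / support constraint), got {prior.family!r}"
            )
        if key == "rho" and (prior.lower < -1.0 or prior.upper > 1.0):
            raise ValueError(f"prior for {name!r} must keep |rho| < 1")
        if key == "t0" and (prior.lower < 0.0 or prior.upper > 366.0):
            raise ValueError(f"prior for {name!r} must keep t0 within [0, n)")

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key):
        return self._priors[key]

    def __iter__(self):
        return iter(self._priors)

    def __len__(self):
        return len(self._priors)

    def replace(self, **overrides) -> "PriorSpec":
        """Return a copy with the named priors overridden (validated)."""
        new = dict(self._priors)
        for name, prior in overrides.items():
            if name not in new:
                raise KeyError(f"unknown parameter {name!r}")
            new[name] = prior
        return PriorSpec(new)

    def describe(self) -> str:
        lines = []
        for name, p in sorted(self._priors.items()):
            if p.family == "uniform":
                lines.append(f"{name}: Uniform({np.min(p.loc):g}, {np.max(p.scale):g})")
            elif p.family == "halfnormal":
                lines.append(f"{name}: HalfNormal(sd={np.max(p.scale):g})")
            else:
                loc = p.loc if p.loc.ndim == 0 else "per-window"
                lines.append(f"{name}: Normal({loc}, sd={np.max(p.scale):g})")
        return "\n".join(lines)

    # joint prior density --------------------------------------------------
    def log_prior(self, state, config: ModelConfig) -> float:
        lp = 0.0
        th = state.theta
        lp += self["theta0"].logpdf(th.theta0)
        lp += self["theta1"].logpdf(th.theta1)
        if not config.share_intercept:
            lp += self["theta0p"].logpdf(th.theta0p)
        lp += self["theta1p"].logpdf(th.theta1p)
        lp += self["sigma_max"].logpdf(th.sigma_max)
        lp += self["sigma_min"].logpdf(th.sigma_min)
        if config.use_discharge:
            lp += self["theta2"].logpdf(th.theta2)
            lp += self["theta2p"].logpdf(th.theta2p)
        for prefix, sp, ar in (
            ("at", state.at_seasonal, state.at_ar1),
            ("q", state.q_seasonal, state.q_ar1),
        ):
            if sp is None:
                continue
            lp += self[f"alpha_{prefix}"].logpdf(sp.alpha)
            lp += self[f"beta_{prefix}"].logpdf(sp.beta)
            lp += self[f"t0_{prefix}"].logpdf(sp.t0)
            lp += self[f"rho_{prefix}"].logpdf(ar.rho)
            lp += self[f"sigma_{prefix}"].logpdf(ar.sigma)
        lp += self["t0_wt"].logpdf(state.wt_t0)
        if config.variant == "M2":
            lp += self["delta"].logpdf(state.link.delta)
            lp += self["sigma_zeta"].logpdf(state.link.sigma_zeta)
            if config.use_discharge:
                lp += self["gamma"].logpdf(state.link.gamma)
        else:
            lp += self["rho_wt"].logpdf(state.wt_ar1.rho)
            lp += self["sigma_wt"].logpdf(state.wt_ar1.sigma)
        return float(lp)


def default_priors(
    data: Mapping[str, DailySeries],
    windows: WindowIndex,
    config: ModelConfig,
) -> PriorSpec:
    """Weakly-informative defaults scaled to the data.

    Regression coefficients and the residual-link gains get Normal(0, 10);
    autocorrelations Uniform(-1, 1); every SD a half-Normal whose scale is
    twice the empirical residual SD of the relevant series; covariate window
    means a Normal centred on the empirical window mean (SD 10); amplitudes
    HalfNormal(10); phases Uniform over the year.  All entries can be
    overridden through :meth:`PriorSpec.replace`.
    """
    priors: dict = {}
    wide = 10.0
    for nm in ("theta0", "theta1", "theta2", "theta0p", "theta1p", "theta2p", "delta", "gamma"):
        priors[nm] = Prior("normal", 0.0, wide)

    n_max = float(windows.n_per_year.max())
    stats = {}
    for key, prefix in (("AT", "at"), ("LOGQ", "q"), ("WT", "wt")):
        if key == "LOGQ" and not config.use_discharge:
            continue
        if key not in data:
            raise KeyError(f"missing series {key}")
        alpha_hat, t0_hat, resid_sd, _ = _empirical_sine_stats(data[key], windows)
        stats[prefix] = (alpha_hat, t0_hat, resid_sd)
        priors[f"t0_{prefix}"] = Prior("uniform", 0.0, n_max)
        if prefix != "wt":
            priors[f"alpha_{prefix}"] = Prior("normal", alpha_hat, wide)
            priors[f"beta_{prefix}"] = Prior("halfnormal", scale=wide)
            priors[f"rho_{prefix}"] = Prior("uniform", -1.0, 1.0)
            priors[f"sigma_{prefix}"] = Prior("halfnormal", scale=2.0 * resid_sd)

    wt_sd = stats["wt"][2]
    priors["sigma_zeta"] = Prior("halfnormal", scale=2.0 * wt_sd)
    priors["rho_wt"] = Prior("uniform", -1.0, 1.0)
    priors["sigma_wt"] = Prior("halfnormal", scale=2.0 * wt_sd)
    # between-window spread of WT extrema around the regression line
    priors["sigma_max"] = Prior("halfnormal", scale=2.0 * max(wt_sd, 1.0))
    priors["sigma_min"] = Prior("halfnormal", scale=2.0 * max(wt_sd, 1.0))
    return PriorSpec(priors)
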