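"""Core model equations for the stream-temperature decomposition model.

Pure, stateless building blocks shared by the simulator, the MCMC engine and
the prediction code:

* calendar half-year windows and the annual sinusoid
  ``X[y, t] = alpha[y] + beta[y] * sin(2*pi/n * (t - t0)) + eps[t]``,
* the max/min reparametrisation ``max_y = alpha_y + beta_y``,
  ``min_y = alpha_y - beta_y`` used to regress water-temperature window
  extrema on those of the covariates,
* zero-mean stationary AR(1) residual processes,
* the short-term residual link
  ``eps_WT = delta * eps_AT + gamma * eps_Q * sin(2*pi/n*(t - t0 + n/2)) + zeta``
  whose sine modifier strictly antiphases the water-temperature seasonal
  signal (high flow cools in summer, warms in winter),
* the joint log posterior assembling all of the above for model variants
  M1 (AR(1) water-temperature residuals) and M2 (covariate-linked residuals).

Everything here operates on plain numpy arrays and small frozen dataclasses;
no randomness except the explicitly seeded AR(1) simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("streamtemp")

VariableKind = Literal["WT", "AT", "LOGQ"]

#: sanity bounds (degrees C) for observed water / air temperature
TEMP_BOUNDS = (-30.0, 45.0)

__all__ = [
    "DailySeries",
    "WindowIndex",
    "SeasonalParams",
    "ExtremaParams",
    "AR1Params",
    "ThetaParams",
    "ShortTermLinkParams",
    "ModelConfig",
    "ModelState",
    "build_windows",
    "seasonal_signal",
    "seasonal_curve",
    "flow_modifier",
    "to_extrema",
    "from_extrema",
    "ar1_logdensity",
    "ar1_simulate",
    "wt_extrema_mean",
    "short_term_link",
    "joint_logposterior",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


def _as_dates(dates) -> np.ndarray:
    arr = np.asarray(pd.DatetimeIndex(dates).values.astype("datetime64[D]"))
    return arr


@dataclass
class DailySeries:
    """A single daily-resolution variable with an explicit missingness mask.

    Parameters
    ----------
    dates
        Strictly increasing, gap-free calendar days.  Gaps in the record are
        represented by ``observed_mask`` being ``False``, never by absent rows.
    values
        Daily values; entries at unobserved days may be NaN.  Units are
        degrees C for ``WT``/``AT`` and natural-log m^3/s for ``LOGQ``.
    observed_mask
        Boolean per day; ``True`` where the value was actually measured.
    kind
        One of ``"WT"``, ``"AT"``, ``"LOGQ"``.
    """

    dates: np.ndarray
    values: np.ndarray
    observed_mask: np.ndarray
    kind: VariableKind

    def __post_init__(self) -> None:
        self.dates = _as_dates(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        n = len(self.dates)
        if n == 0:
            raise ValueError("DailySeries needs at least one day")
        if not (len(self.values) == len(self.observed_mask) == n):
            raise ValueError("dates, values and observed_mask must share length")
        if self.kind not in ("WT", "AT", "LOGQ"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        deltas = np.diff(self.dates).astype("timedelta64[D]").astype(int)
        if np.any(deltas <= 0):
            bad = self.dates[1:][deltas <= 0][0]
            raise ValueError(f"dates must be strictly increasing (at {bad})")
        if np.any(deltas != 1):
            bad = self.dates[1:][deltas != 1][0]
            raise ValueError(
                f"dates must be consecutive calendar days (gap before {bad}); "
                "represent data gaps with observed_mask, not missing rows"
            )
        obs = self.values[self.observed_mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError(f"{self.kind}: observed values must be finite")
        if self.kind in ("WT", "AT") and obs.size:
            lo, hi = TEMP_BOUNDS
            if obs.min() <= lo or obs.max() >= hi:
                raise ValueError(
                    f"{self.kind}: observed values outside sanity bounds {TEMP_BOUNDS}"
                )

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_observed(self) -> int:
        return int(self.observed_mask.sum())

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.n_observed / len(self)


@dataclass
class WindowIndex:
    """Assignment of every day to a contiguous six-month calendar window.

    Windows are calendar half-years (Jan 1 - Jun 30, Jul 1 - Dec 31); partial
    windows at the series edges are kept but flagged.  ``n_per_year`` is the
    true number of days (365 or 366) in each day's calendar year.
    """

    dates: np.ndarray  # per day
    window_id: np.ndarray  # per day, 0-based
    day_of_year: np.ndarray  # per day, 1-based
    n_per_year: np.ndarray  # per day, 365 or 366
    starts: np.ndarray  # per window, index of first day
    stops: np.ndarray  # per window, one past last day
    labels: list  # per window, e.g. "2001H1"
    is_partial: np.ndarray  # per window

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def window_length(self, y: int) -> int:
        return int(self.stops[y] - self.starts[y])


def build_windows(dates) -> WindowIndex:
    """Partition consecutive calendar days into half-year windows.

    Raises ``ValueError`` (reporting the offending date) on duplicated or
    non-consecutive input.
    """
    dates = _as_dates(dates)
    if len(dates) == 0:
        raise ValueError("empty date range")
    deltas = np.diff(dates).astype("timedelta64[D]").astype(int)
    if np.any(deltas != 1):
        bad = dates[1:][deltas != 1][0]
        raise ValueError(f"dates must be consecutive and unique (at {bad})")
    idx = pd.DatetimeIndex(dates)
    years = idx.year.to_numpy()
    half = (idx.month.to_numpy() >= 7).astype(int)
    key = years * 2 + half
    # contiguous runs of (year, half)
    changes = np.flatnonzero(np.diff(key)) + 1
    starts = np.concatenate([[0], changes])
    stops = np.concatenate([changes, [len(dates)]])
    wid = np.repeat(np.arange(len(starts)), stops - starts)
    labels = [f"{years[s]}H{half[s] + 1}" for s in starts]
    leap = np.asarray(idx.is_leap_year)
    n_per_year = np.where(leap, 366, 365).astype(int)
    # a window is full when it spans its entire calendar half-year
    full_len = np.empty(len(starts), dtype=int)
    for k, s in enumerate(starts):
        y, h = years[s], half[s]
        if h == 0:
            full_len[k] = 182 if leap[s] else 181  # Jan 1 .. Jun 30
        else:
            full_len[k] = 184  # Jul 1 .. Dec 31
    is_partial = (stops - starts) != full_len
    if is_partial.any():
        logger.debug(
            "windows %s are partial (series edge)",
            [labels[k] for k in np.flatnonzero(is_partial)],
        )
    return WindowIndex(
        dates=dates,
        window_id=wid,
        day_of_year=idx.dayofyear.to_numpy(),
        n_per_year=n_per_year,
        starts=starts,
        stops=stops,
        labels=labels,
        is_partial=is_partial,
    )


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class SeasonalParams:
    """Per-window mean/amplitude plus a per-series phase.

    ``beta >= 0`` and ``t0 in [0, n)`` resolve the sign/phase ambiguity of
    ``alpha + beta * sin``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    t0: float
    n_per_year: int = 365

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have one entry per window")
        if np.any(self.beta < 0):
            raise ValueError("window amplitudes beta must be nonnegative")
        if not (0 <= self.t0 < self.n_per_year):
            raise ValueError("t0 must lie in [0, n_per_year)")


@dataclass
class ExtremaParams:
    """Window seasonal extrema ``max_y = alpha_y + beta_y``, ``min_y = alpha_y - beta_y``."""

    max_y: np.ndarray
    min_y: np.ndarray

    def __post_init__(self) -> None:
        self.max_y = np.atleast_1d(np.asarray(self.max_y, dtype=float))
        self.min_y = np.atleast_1d(np.asarray(self.min_y, dtype=float))
        if self.max_y.shape != self.min_y.shape:
            raise ValueError("max_y and min_y must share shape")
        if np.any(self.max_y < self.min_y):
            raise ValueError("window maxima must not be below minima")


def to_extrema(sp: SeasonalParams) -> ExtremaParams:
    return ExtremaParams(max_y=sp.alpha + sp.beta, min_y=sp.alpha - sp.beta)


def from_extrema(ep: ExtremaParams, t0: float, n_per_year: int = 365) -> SeasonalParams:
    return SeasonalParams(
        alpha=(ep.max_y + ep.min_y) / 2.0,
        beta=(ep.max_y - ep.min_y) / 2.0,
        t0=t0,
        n_per_year=n_per_year,
    )


@dataclass
class AR1Params:
    """Stationary zero-mean AR(1): autocorrelation ``rho`` and innovation SD ``sigma``."""

    rho: float
    sigma: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("AR1 requires |rho| < 1 (stationarity)")
        if not self.sigma > 0:
            raise ValueError("AR1 requires sigma > 0")

    @property
    def stationary_var(self) -> float:
        return self.sigma**2 / (1.0 - self.rho**2)


@dataclass
class ThetaParams:
    """Regression of WT window extrema on covariate extrema.

    ``mu_max = theta0 + theta1*max_AT + theta2*min_Q`` and
    ``mu_min = theta0p + theta1p*min_AT + theta2p*max_Q``; the flow slopes are
    identically zero when the model runs without discharge.
    """

    theta0: float
    theta1: float
    theta0p: float
    theta1p: float
    theta2: float = 0.0
    theta2p: float = 0.0
    sigma_max: float = 1.0
    sigma_min: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma_max > 0 and self.sigma_min > 0):
            raise ValueError("extrema regression SDs must be positive")


@dataclass
class ShortTermLinkParams:
    """Daily-deviation link: WT residual mean = delta*eps_AT + gamma*modifier*eps_Q."""

    delta: float
    gamma: float = 0.0
    sigma_zeta: float = 0.5

    def __post_init__(self) -> None:
        if not self.sigma_zeta > 0:
            raise ValueError("white-noise SD sigma_zeta must be positive")


# ---------------------------------------------------------------------------
# deterministic pieces
# ---------------------------------------------------------------------------


def _check_day_index(windows: WindowIndex, t) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=int))
    if t.size and (t.min() < 0 or t.max() >= windows.n_days):
        raise IndexError(
            f"day index outside the known windows (0..{windows.n_days - 1})"
        )
    return t


def seasonal_signal(sp: SeasonalParams, windows: WindowIndex, t):
    """Seasonal mean ``alpha_y + beta_y * sin(2*pi/n * (doy - t0))`` at day index ``t``.

    ``t`` indexes days of the window calendar; the sine argument uses the
    1-based day-of-year and that calendar year's length (365 or 366).
    """
    t_arr = _check_day_index(windows, t)
    wid = windows.window_id[t_arr]
    if wid.max(initial=-1) >= len(sp.alpha):
        raise IndexError("SeasonalParams does not cover all requested windows")
    doy = windows.day_of_year[t_arr]
    n = windows.n_per_year[t_arr]
    vals = sp.alpha[wid] + sp.beta[wid] * np.sin(2.0 * np.pi / n * (doy - sp.t0))
    return vals if np.ndim(t) else float(vals[0])


def seasonal_curve(alpha, beta, t0, windows: WindowIndex) -> np.ndarray:
    """Vectorised seasonal mean over every day of ``windows`` (internal fast path)."""
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    wid = windows.window_id
    s = np.sin(2.0 * np.pi / windows.n_per_year * (windows.day_of_year - t0))
    return alpha[wid] + beta[wid] * s, s


def flow_modifier(day_of_year, n_per_year, t0: float) -> np.ndarray:
    """Sine modifier of the flow deviation term, ``sin(2*pi/n*(doy - t0 + n/2))``.

    Equal to minus the seasonal sine: exactly -1 at the water-temperature
    seasonal maximum and +1 at the minimum, so that high flow cools in summer
    and warms in winter.
    """
    doy = np.asarray(day_of_year, dtype=float)
    n = np.asarray(n_per_year, dtype=float)
    return np.sin(2.0 * np.pi / n * (doy - t0 + n / 2.0))


# ---------------------------------------------------------------------------
# AR(1) residual process
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2.0 * np.pi))


def ar1_logdensity(eps: np.ndarray, p: AR1Params) -> float:
    """Log density of a zero-mean stationary AR(1) path.

    The first point follows the stationary law N(0, sigma^2/(1-rho^2)); each
    subsequent point is N(rho * eps[t-1], sigma^2).
    """
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 1 or eps.size == 0:
        raise ValueError("eps must be a nonempty vector")
    v0 = p.stationary_var
    ll = -0.5 * (_LOG2PI + np.log(v0) + eps[0] ** 2 / v0)
    if eps.size > 1:
        innov = eps[1:] - p.rho * eps[:-1]
        ll += -0.5 * (
            (eps.size - 1) * (_LOG2PI + 2.0 * np.log(p.sigma))
            + np.dot(innov, innov) / p.sigma**2
        )
    return float(ll)


def ar1_simulate(length: int, p: AR1Params, seed=None) -> np.ndarray:
    """Simulate a stationary zero-mean AR(1) path, reproducible given a seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(length)
    eps = np.empty(length)
    eps[0] = z[0] * np.sqrt(p.stationary_var)
    for t in range(1, length):
        eps[t] = p.rho * eps[t - 1] + p.sigma * z[t]
    return eps


# ---------------------------------------------------------------------------
# linked regressions
# ---------------------------------------------------------------------------


def wt_extrema_mean(theta: ThetaParams, max_at, min_at, min_q=None, max_q=None):
    """Mean of the WT window extrema regressions.

    Returns ``(mu_max, mu_min)`` with ``mu_max = theta0 + theta1*max_AT +
    theta2*min_Q`` and ``mu_min = theta0p + theta1p*min_AT + theta2p*max_Q``.
    WT extrema are then Normal(mu, sigma^2) around these means.  Discharge
    arguments are on the natural-log scale; omit them for the no-flow variant.
    """
    max_at = np.asarray(max_at, dtype=float)
    min_at = np.asarray(min_at, dtype=float)
    if not (np.all(np.isfinite(max_at)) and np.all(np.isfinite(min_at))):
        raise ValueError("air-temperature extrema must be finite")
    if min_q is None or max_q is None:
        if theta.theta2 != 0.0 or theta.theta2p != 0.0:
            raise ValueError("flow slopes must be zero when no discharge is supplied")
        min_q = max_q = 0.0
    min_q = np.asarray(min_q, dtype=float)
    max_q = np.asarray(max_q, dtype=float)
    mu_max = theta.theta0 + theta.theta1 * max_at + theta.theta2 * min_q
    mu_min = theta.theta0p + theta.theta1p * min_at + theta.theta2p * max_q
    return mu_max, mu_min


def short_term_link(
    link: ShortTermLinkParams,
    eps_at,
    eps_q,
    day_of_year,
    t0: float,
    n_per_year=365,
):
    """Mean of the daily WT deviation given covariate deviations.

    ``delta * eps_AT + gamma * eps_Q * sin(2*pi/n*(doy - t0 + n/2))``; the WT
    daily deviation is this mean plus white noise zeta ~ N(0, sigma_zeta^2).
    ``t0`` is the *water-temperature* phase: the modifier antiphases the WT
    seasonal signal.  ``eps_q`` may be None/empty when no discharge is used.
    """
    eps_at = np.asarray(eps_at, dtype=float)
    if eps_q is None or np.size(eps_q) == 0:
        return link.delta * eps_at
    eps_q = np.asarray(eps_q, dtype=float)
    if eps_q.shape != eps_at.shape:
        raise ValueError("eps_at and eps_q must share shape")
    mod = flow_modifier(day_of_year, n_per_year, t0)
    return link.delta * eps_at + link.gamma * eps_q * mod


# ---------------------------------------------------------------------------
# joint posterior
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Structural switches of the model.

    variant
        ``"M2"`` links daily WT deviations to covariate deviations (the
        extended model); ``"M1"`` models them as an AR(1) process.
    use_discharge
        Whether a log-discharge series takes part (flow slopes/gain are fixed
        to zero otherwise).
    share_intercept
        Use a single intercept theta0 in both extrema regressions, the form
        in which the equations are usually printed; the default estimates two.
    """

    variant: Literal["M1", "M2"] = "M2"
    use_discharge: bool = True
    share_intercept: bool = False


@dataclass
class ModelState:
    """One complete point of the joint parameter/latent space."""

    at_seasonal: SeasonalParams
    at_ar1: AR1Params
    wt_extrema: ExtremaParams
    wt_t0: float
    theta: ThetaParams
    q_seasonal: Optional[SeasonalParams] = None
    q_ar1: Optional[AR1Params] = None
    link: Optional[ShortTermLinkParams] = None  # M2
    wt_ar1: Optional[AR1Params] = None  # M1
    # imputations at unobserved days, in series order
    wt_missing: Optional[np.ndarray] = None
    at_missing: Optional[np.ndarray] = None
    q_missing: Optional[np.ndarray] = None


def _complete(series: DailySeries, imputed: Optional[np.ndarray]) -> np.ndarray:
    x = series.values.copy()
    gaps = ~series.observed_mask
    if gaps.any():
        if imputed is None or len(np.atleast_1d(imputed)) != int(gaps.sum()):
            raise ValueError(
                f"{series.kind}: imputations required for {int(gaps.sum())} missing days"
            )
        x[gaps] = imputed
    return x


def _normal_ll(resid: np.ndarray, sd: float) -> float:
    resid = np.asarray(resid, dtype=float)
    return float(
        -0.5 * resid.size * (_LOG2PI + 2.0 * np.log(sd))
        - 0.5 * np.dot(resid, resid) / sd**2
    )


def joint_logposterior(
    data: Mapping[str, DailySeries],
    windows: WindowIndex,
    state: ModelState,
    config: ModelConfig,
    priors=None,
) -> float:
    """Joint log posterior of the full model at one state.

    Assembles the seasonal decomposition of every series, the AR(1) residual
    densities of the covariates, the extrema regressions, and the daily WT
    law (covariate link + white noise for M2, AR(1) for M1), plus prior terms
    when a prior specification is given (any object with a
    ``log_prior(state, config)`` method).  Parameter values violating the
    type invariants yield ``-inf`` rather than an exception, so samplers can
    treat them as rejected states.

    Missing observations contribute no likelihood term of their own: the
    imputations stored in ``state`` stand in for them, which is the standard
    data-augmentation form of the same posterior.
    """
    wt, at = data["WT"], data["AT"]
    if len(wt) != windows.n_days or len(at) != windows.n_days:
        raise ValueError("all series must share the window calendar")
    use_q = config.use_discharge
    if use_q and "LOGQ" not in data:
        raise ValueError("use_discharge=True but no LOGQ series supplied")

    try:
        x_at = _complete(at, state.at_missing)
        x_wt = _complete(wt, state.wt_missing)
        m_at, s_at = seasonal_curve(
            state.at_seasonal.alpha, state.at_seasonal.beta, state.at_seasonal.t0, windows
        )
        eps_at = x_at - m_at
        lp = ar1_logdensity(eps_at, state.at_ar1)

        if use_q:
            q = data["LOGQ"]
            if len(q) != windows.n_days:
                raise ValueError("all series must share the window calendar")
            x_q = _complete(q, state.q_missing)
            m_q, _ = seasonal_curve(
                state.q_seasonal.alpha, state.q_seasonal.beta, state.q_seasonal.t0, windows
            )
            eps_q = x_q - m_q
            lp += ar1_logdensity(eps_q, state.q_ar1)
        else:
            eps_q = None
            if state.link is not None and state.link.gamma != 0.0:
                return -np.inf
            if state.theta.theta2 != 0.0 or state.theta.theta2p != 0.0:
                return -np.inf

        # extrema regressions (Eq 2 analogue)
        th = state.theta
        if config.share_intercept and th.theta0p != th.theta0:
            return -np.inf
        at_ex = to_extrema(state.at_seasonal)
        if use_q:
            q_ex = to_extrema(state.q_seasonal)
            mu_max, mu_min = wt_extrema_mean(
                th, at_ex.max_y, at_ex.min_y, q_ex.min_y, q_ex.max_y
            )
        else:
            mu_max, mu_min = wt_extrema_mean(th, at_ex.max_y, at_ex.min_y)
        lp += _normal_ll(state.wt_extrema.max_y - mu_max, th.sigma_max)
        lp += _normal_ll(state.wt_extrema.min_y - mu_min, th.sigma_min)

        # daily WT law
        wt_sp = from_extrema(state.wt_extrema, state.wt_t0)
        m_wt, s_wt = seasonal_curve(wt_sp.alpha, wt_sp.beta, state.wt_t0, windows)
        eps_wt = x_wt - m_wt
        if config.variant == "M2":
            link = state.link
            mod = flow_modifier(windows.day_of_year, windows.n_per_year, state.wt_t0)
            mean = link.delta * eps_at
            if use_q:
                mean = mean + link.gamma * eps_q * mod
            lp += _normal_ll(eps_wt - mean, link.sigma_zeta)
        elif config.variant == "M1":
            lp += ar1_logdensity(eps_wt, state.wt_ar1)
        else:
            raise ValueError(f"unknown model variant {config.variant!r}")
    except ValueError as err:  # invariant violated mid-sampling -> rejected state
        msg = str(err)
        if ("must share" in msg) or ("imputations required" in msg) or ("calendar" in msg):
            raise
        return -np.inf

    if priors is not None:
        lp += priors.log_prior(state, config)
    return float(lp)
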