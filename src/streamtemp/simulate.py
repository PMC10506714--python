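"""Forward simulation of daily WT/AT/discharge series with known parameters.

The generator runs the model forward: per-window means and amplitudes are
drawn around stated scenario means, air temperature and log-discharge get
AR(1) daily residuals, water-temperature window extrema follow the extrema
regression, and daily water temperature follows either the covariate-linked
residual law (M2) or an AR(1) process (M1).  Missingness with geometric gap
lengths is applied last.  The full truth record is returned so that
parameter-recovery, calibration and cross-validation experiments can compare
posteriors against known values.

The default scenario mimics the scale of a 13-year medium-sized temperate
river record: mean water temperature ~12.9 degC, mean air temperature
~12.4 degC, mean discharge ~5 m^3/s, ~27% of water-temperature days missing
in multi-week gaps, and daily-deviation gains delta=0.6, gamma=0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np

from .core import (
    AR1Params,
    DailySeries,
    ModelConfig,
    WindowIndex,
    ar1_simulate,
    build_windows,
    flow_modifier,
    seasonal_curve,
    wt_extrema_mean,
    ThetaParams,
    ShortTermLinkParams,
)

logger = logging.getLogger("streamtemp")

__all__ = ["MissingSpec", "SimulationScenario", "simulate_dataset", "apply_missingness"]


@dataclass
class MissingSpec:
    """Per-series missingness: overall fraction and mean geometric gap length (days)."""

    fraction: float = 0.0
    mean_gap: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("missing fraction must lie in [0, 1)")
        if self.mean_gap < 1.0:
            raise ValueError("mean gap length must be >= 1 day")


@dataclass
class SimulationScenario:
    """True parameter values and data shape for one synthetic dataset."""

    years: int = 13
    start: str = "1995-01-01"
    variant: str = "M2"
    use_discharge: bool = True
    seed: int = 0

    # seasonal structure: window means/amplitudes drawn around these
    at_alpha_mean: float = 12.39
    at_beta_mean: float = 6.5
    at_alpha_sd: float = 0.7
    at_beta_sd: float = 0.5
    at_t0: float = 110.0
    q_alpha_mean: float = 1.6  # natural-log m^3/s (~5 m^3/s)
    q_beta_mean: float = 0.8
    q_alpha_sd: float = 0.25
    q_beta_sd: float = 0.15
    q_t0: float = 292.5  # discharge peaks in winter, antiphasing temperature
    wt_t0: float = 110.0
    alpha_trend: float = 0.0  # optional linear warming trend, degC per year

    # AR(1) daily residuals of the covariates
    rho_at: float = 0.8
    sigma_at: float = 1.2
    rho_q: float = 0.9
    sigma_q: float = 0.15

    # extrema regression (WT window extrema on covariate extrema)
    theta0: float = 4.0
    theta1: float = 0.75
    theta2: float = -0.4
    theta0p: float = 2.8
    theta1p: float = 0.7
    theta2p: float = 0.4
    sigma_max: float = 0.5
    sigma_min: float = 0.5

    # daily WT law
    delta: float = 0.6
    gamma: float = 0.5
    sigma_zeta: float = 0.5  # M2 white noise, degC
    rho_wt: float = 0.8  # M1 only
    sigma_wt: float = 0.6  # M1 only

    wt_missing: MissingSpec = field(default_factory=lambda: MissingSpec(0.2698, 30.0))
    at_missing: MissingSpec = field(default_factory=lambda: MissingSpec(0.0063, 3.0))
    q_missing: MissingSpec = field(default_factory=lambda: MissingSpec(0.0105, 5.0))

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("need at least one year of data")
        if self.variant not in ("M1", "M2"):
            raise ValueError("variant must be 'M1' or 'M2'")
        if not abs(self.rho_at) < 1 or not abs(self.rho_q) < 1 or not abs(self.rho_wt) < 1:
            raise ValueError("autocorrelations must satisfy |rho| < 1")
        for nm in ("sigma_at", "sigma_q", "sigma_max", "sigma_min", "sigma_zeta", "sigma_wt"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        for nm in ("at_beta_mean", "q_beta_mean"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be nonnegative")
        if not self.use_discharge:
            # flow pathways are structurally absent
            object.__setattr__(self, "gamma", 0.0)
            object.__setattr__(self, "theta2", 0.0)
            object.__setattr__(self, "theta2p", 0.0)

    @property
    def config(self) -> ModelConfig:
        return ModelConfig(variant=self.variant, use_discharge=self.use_discharge)


def _draw_window_params(rng, windows: WindowIndex, mean, sd, beta_mean, beta_sd,
                        trend_per_year: float = 0.0):
    W = windows.n_windows
    years = np.arange(W) / 2.0  # windows are half-years
    alpha = mean + trend_per_year * (years - years.mean()) + sd * rng.standard_normal(W)
    beta = beta_mean + beta_sd * rng.standard_normal(W)
    # amplitudes are nonnegative by model convention
    beta = np.abs(beta)
    return alpha, beta


def simulate_dataset(scenario: SimulationScenario):
    """Generate one synthetic dataset plus its truth record.

    Returns ``(data, truth)`` where ``data`` maps ``"WT"``/``"AT"`` (and
    ``"LOGQ"`` when discharge is used) to :class:`DailySeries` and ``truth``
    is a flat dict of every generating value (scalars plus per-window
    arrays).  Bit-reproducible for a given scenario seed.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    start = np.datetime64(s.start, "D")
    end = np.datetime64(str(int(s.start[:4]) + s.years) + s.start[4:], "D")
    dates = np.arange(start, end)
    windows = build_windows(dates)
    T = len(dates)

    truth: dict = {}

    # --- covariates -------------------------------------------------------
    a_at, b_at = _draw_window_params(
        rng, windows, s.at_alpha_mean, s.at_alpha_sd, s.at_beta_mean, s.at_beta_sd,
        s.alpha_trend,
    )
    eps_at = ar1_simulate(T, AR1Params(s.rho_at, s.sigma_at), rng)
    m_at, _ = seasonal_curve(a_at, b_at, s.at_t0, windows)
    x_at = m_at + eps_at
    truth.update(alpha_at=a_at, beta_at=b_at, t0_at=s.at_t0,
                 rho_at=s.rho_at, sigma_at=s.sigma_at)

    if s.use_discharge:
        a_q, b_q = _draw_window_params(
            rng, windows, s.q_alpha_mean, s.q_alpha_sd, s.q_beta_mean, s.q_beta_sd
        )
        eps_q = ar1_simulate(T, AR1Params(s.rho_q, s.sigma_q), rng)
        m_q, _ = seasonal_curve(a_q, b_q, s.q_t0, windows)
        x_q = m_q + eps_q
        truth.update(alpha_q=a_q, beta_q=b_q, t0_q=s.q_t0,
                     rho_q=s.rho_q, sigma_q=s.sigma_q)
    else:
        eps_q = None

    # --- WT window extrema ------------------------------------------------
    theta = ThetaParams(s.theta0, s.theta1, s.theta0p, s.theta1p,
                        s.theta2, s.theta2p, s.sigma_max, s.sigma_min)
    max_at, min_at = a_at + b_at, a_at - b_at
    if s.use_discharge:
        mu_max, mu_min = wt_extrema_mean(theta, max_at, min_at, a_q - b_q, a_q + b_q)
    else:
        mu_max, mu_min = wt_extrema_mean(theta, max_at, min_at)
    for _ in range(100):
        max_wt = mu_max + s.sigma_max * rng.standard_normal(windows.n_windows)
        min_wt = mu_min + s.sigma_min * rng.standard_normal(windows.n_windows)
        bad = max_wt < min_wt
        if not bad.any():
            break
        mu_gap = mu_max - mu_min
        logger.warning("redrawing %d WT extrema pairs with max < min "
                       "(mean regression gap %.2f)", int(bad.sum()), float(mu_gap.mean()))
    else:
        raise RuntimeError("could not draw valid WT extrema; scenario degenerate")
    a_wt, b_wt = (max_wt + min_wt) / 2.0, (max_wt - min_wt) / 2.0
    truth.update(max_wt=max_wt, min_wt=min_wt, alpha_wt=a_wt, beta_wt=b_wt,
                 t0_wt=s.wt_t0, theta0=s.theta0, theta1=s.theta1,
                 theta0p=s.theta0p, theta1p=s.theta1p,
                 sigma_max=s.sigma_max, sigma_min=s.sigma_min)
    if s.use_discharge:
        truth.update(theta2=s.theta2, theta2p=s.theta2p)

    # --- daily WT ---------------------------------------------------------
    m_wt, _ = seasonal_curve(a_wt, b_wt, s.wt_t0, windows)
    if s.variant == "M2":
        link = ShortTermLinkParams(s.delta, s.gamma, s.sigma_zeta)
        mean_dev = link.delta * eps_at
        if s.use_discharge:
            mod = flow_modifier(windows.day_of_year, windows.n_per_year, s.wt_t0)
            mean_dev = mean_dev + link.gamma * eps_q * mod
        x_wt = m_wt + mean_dev + s.sigma_zeta * rng.standard_normal(T)
        truth.update(delta=s.delta, sigma_zeta=s.sigma_zeta)
        if s.use_discharge:
            truth.update(gamma=s.gamma)
    else:
        eps_wt = ar1_simulate(T, AR1Params(s.rho_wt, s.sigma_wt), rng)
        x_wt = m_wt + eps_wt
        truth.update(rho_wt=s.rho_wt, sigma_wt=s.sigma_wt)

    # --- missingness ------------------------------------------------------
    data = {}
    for kind, values, spec in (
        ("WT", x_wt, s.wt_missing),
        ("AT", x_at, s.at_missing),
        ("LOGQ", x_q if s.use_discharge else None, s.q_missing),
    ):
        if values is None:
            continue
        mask = _missingness_mask(T, spec.fraction, spec.mean_gap, rng)
        shown = np.where(mask, values, np.nan)
        data[kind] = DailySeries(dates=dates, values=shown, observed_mask=mask, kind=kind)
    logger.info(
        "simulated %d days (%s, discharge=%s): WT %.1f%% missing",
        T, s.variant, s.use_discharge, 100 * data["WT"].missing_fraction,
    )
    return data, truth


def _missingness_mask(T: int, fraction: float, mean_gap: float, rng) -> np.ndarray:
    """Alternating observed/missing runs with geometric lengths.

    Gap lengths are Geometric(1/mean_gap); observed run lengths are geometric
    with mean chosen so the long-run masked fraction matches ``fraction``.
    """
    if fraction <= 0.0:
        return np.ones(T, dtype=bool)
    mean_obs = mean_gap * (1.0 - fraction) / fraction
    p_gap = min(1.0 / mean_gap, 1.0)
    p_obs = min(1.0 / max(mean_obs, 1.0), 1.0)
    mask = np.ones(T, dtype=bool)
    pos = int(rng.geometric(p_obs) * rng.uniform())  # random phase for the first run
    observed = False
    while pos < T:
        run = int(rng.geometric(p_gap if not observed else p_obs))
        if not observed:
            mask[pos:pos + run] = False
        pos += run
        observed = not observed
    return mask


def apply_missingness(series: DailySeries, fraction: float, mean_gap: float = 10.0,
                      seed=None) -> DailySeries:
    """Mask about ``fraction`` of a series' days using geometric gap lengths.

    Already-missing days stay missing.  Deterministic given a seed.
    """
    spec = MissingSpec(fraction, mean_gap)  # validates
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _missingness_mask(len(series), spec.fraction, spec.mean_gap, rng)
    mask &= series.observed_mask
    return DailySeries(
        dates=series.dates,
        values=np.where(mask, series.values, np.nan),
        observed_mask=mask,
        kind=series.kind,
    )
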