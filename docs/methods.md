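# Methods

`streamtemp` implements a hierarchical Bayesian model that links daily stream
water temperature (WT) to air temperature (AT) and, optionally, river
discharge (Q, modelled on the natural-log scale).  This note documents the
model, the sampler, the synthetic-data generator used for validation, and the
numerical choices a user or maintainer may want to question.

## The model

Every series is decomposed into a slowly varying seasonal part and a daily
residual:

```
X[y,t] = alpha_y + beta_y * sin(2*pi/n * (t - t0)) + eps[t]
```

where `y` indexes six-month windows over which the mean `alpha_y` and
amplitude `beta_y` are constant, `t` is the (1-based) day of year, `n` is the
number of days in that calendar year (365 or 366), and `t0` is a per-series
phase in days.  Windows are aligned to calendar half-years (Jan–Jun,
Jul–Dec): the original description fixes only the window length, and calendar
alignment makes windows reproducible across datasets.  Partial windows at the
series edges are kept and flagged; their parameters are estimated like any
other window.

For AT and log-Q the daily residual is a stationary zero-mean AR(1) process
with autocorrelation `rho` and innovation SD `sigma`; the first residual
follows the stationary law N(0, sigma^2/(1-rho^2)).

The WT seasonal component is reparametrised through its window extrema
`max_y = alpha_y + beta_y`, `min_y = alpha_y - beta_y`, which are regressed
on the covariate extrema:

```
max_y^WT ~ Normal(theta0  + theta1  * max_y^AT + theta2  * min_y^Q, sigma_max^2)
min_y^WT ~ Normal(theta0' + theta1' * min_y^AT + theta2' * max_y^Q, sigma_min^2)
```

Warm summers track warm air (`theta1 > 0`); high flow is expected to cool
summers (`theta2 < 0`) and warm winters (`theta2' > 0`).  As usually printed
the two equations share one intercept; the package estimates two by default
(`share_intercept=True` restores the single-intercept form) because the two
regressions describe different halves of the annual cycle and nothing forces
their intercepts to coincide.

Daily WT deviations come in two variants.  The reference variant **M1**
models them as another AR(1) process.  The extended variant **M2** links them
to the covariate deviations:

```
eps[y,t]^WT = delta * eps[y,t]^AT
            + gamma * eps[y,t]^Q * sin(2*pi/n * (t - t0^WT + n/2))
            + zeta[t],        zeta ~ Normal(0, sigma_zeta^2)
```

The sine modifier strictly antiphases the WT seasonal signal (it equals
exactly −1 at the WT seasonal maximum and +1 at the minimum), so a flow
surplus cools the river in summer and warms it in winter, with a smooth
transition between.  Because discharge enters on the log scale, small summer
flow changes matter as much as large winter ones.  Each series carries its
own phase `t0`; the series are linked through the regressions above, not
through a shared phase, and the modifier uses the WT phase since it
antiphases the WT cycle.

Missing observations (in any series) are latent variables sampled jointly
with the parameters, so gap filling, hindcasting and forecasting are all the
same operation: extend the covariate series and treat the unknown WT days as
latent.

## Priors

Priors are weakly informative and scaled to the data (all overridable):
Normal(0, 10) on every regression coefficient and on `delta`/`gamma`;
Uniform(−1, 1) on autocorrelations; HalfNormal(2 × empirical residual SD) on
every innovation SD; Normal(empirical window mean, 10) on covariate window
means; HalfNormal(10) on amplitudes; Uniform(0, n) on phases.  The
constraints `beta_y >= 0` and `t0 in [0, n)` resolve the sign/phase
ambiguity of `alpha + beta*sin`.  WT window extrema need no separate prior:
the extrema regression is their (hierarchical) prior.

## Sampling

The posterior factorises into conditionally Gaussian blocks, so the sampler
is Metropolis-within-Gibbs with exact conjugate updates wherever they exist:

* covariate window means/amplitudes — conjugate Normal (amplitudes truncated
  at zero), updated in an even/odd window checkerboard because AR(1)
  quasi-differences couple adjacent windows; the update includes the
  information flowing back from the extrema regression and (M2) from the
  daily WT equation;
* WT window extrema — conjugate truncated Normal with the extrema regression
  as prior (quasi-differenced for M1);
* `theta`, `delta`, `gamma` — exact multivariate Normal draws;
* `rho` and all `sigma` — univariate slice sampling on cheap sufficient
  statistics;
* latent missing values — exact Gaussian full conditionals, updated in an
  odd/even day checkerboard for the AR(1) cases;
* phases `t0` — random-walk Metropolis with Robbins–Monro scale adaptation
  during burn-in.

Two structural moves deal with known pathologies of this posterior:

1. **Extrema-variance funnel.**  With few windows, the centred Gibbs update
   of `sigma_max`/`sigma_min` can collapse: once the SD is small the extrema
   pin to the regression surface and the SD cannot recover (the classic
   hierarchical funnel).  After the centred update the sampler therefore adds
   an interweaved non-centred step: holding the standardised residuals
   `eta = (max - mu_max)/sigma_max` fixed, the daily WT likelihood is linear
   in `sigma_max`, giving a conjugate truncated-Normal update (the
   `max >= min` constraint translates into per-window linear bounds on the
   SD, which the update respects exactly).
2. **Phase ridges.**  A phase shift can be largely compensated by adjusting
   all window parameters, and — through `delta` — the phases of different
   series compensate each other.  Phase proposals therefore translate the
   window parameters by the shift in their per-window least-squares fit
   between the two phases, and latent values ride along with the surface
   (their residuals are held fixed).  These are shear maps with unit
   Jacobian, so plain Metropolis acceptance remains exact.  A third move
   applies one common shift to all three phases at once, which is the slow
   direction left over after the per-series moves.

Chains are initialised from a per-window least-squares sine fit (phase by
coarse grid search), with overdispersion across chains drawn around it; the
extrema regression is initialised ridge-regularised so that few, collinear
windows cannot produce extreme starting slopes.  Initial states with a
non-finite posterior are rejected with an error.

Two presets are provided: the reference preset (3 chains, burn-in 10000,
10000 kept after thinning by 25) and a desk preset (3 chains, burn-in 2000,
2000 kept, no thinning) sized for interactive work; the replicate experiments
in the test suite use the desk preset on four-year series, which keeps a full
recovery study within minutes while leaving effective sample sizes in the
tens-to-hundreds for the slowest-moving parameters (phases and extrema-
regression slopes) and far higher for the daily-scale parameters.
Convergence is summarised per monitored parameter by split-R̂ and bulk ESS
(arviz), flagging R̂ > 1.1 or ESS < 100.

## Prediction

`predict` works per posterior draw.  Windows present in the training period
reuse that draw's window parameters and latent values.  New windows (beyond
the training period) get covariate means/amplitudes sampled from their
within-window conditional given the supplied covariate data and the draw's
`(t0, rho, sigma)` — observed runs are quasi-differenced, each run restarting
from the stationary law, which ignores the weak residual coupling across
window boundaries — and WT extrema drawn from the extrema regression.  Daily
values then follow the variant's residual law: the covariate-linked mean plus
white noise for M2, or an AR(1) path continued from the last known training
residual for M1 (started from the stationary law when the target is not
contiguous with training).  The point prediction (`mean` column) averages the
conditional-mean surface over draws; quantiles summarise full predictive
draws including observation noise.  Observed WT days pass through unchanged
and are flagged.

`project_warming` uses the closed form implied by the model: a uniform AT
warming `D` shifts both AT window extrema by `D`, moving the WT extrema
regression means by `theta1*D` and `theta1'*D`, hence the annual mean by
`((theta1 + theta1')/2)*D` — exactly, draw by draw.  Daily deviations are
unchanged by a uniform shift, so `delta` contributes nothing to mean
warming; the projection deliberately carries only the seasonal pathway, and
seasonal (max/min) warming is reported alongside.  This is an interpretation
of "projecting WT from AT warming": no formula for a daily-deviation
contribution exists in the source description, and under a uniform offset
that contribution is identically zero.

## Evaluation

* **Chi-square posterior check**: per draw, the conditional law of each
  observed WT day given the parameters (Normal(seasonal + link, sigma_zeta^2)
  for M2; the one-step AR(1) law for M1, stationary at the first day or
  after the start) gives the discrepancy of the observations and of a
  replicated dataset; the Bayesian p-value is the fraction of draws where the
  replicate exceeds the observed.  Values near 0.5 indicate congruency,
  values around 0.95/0.05 are warnings.
* **DIC**: deviance is −2 × the observed-WT log likelihood under the same
  conditional law, so both variants are scored on identical observations
  (covariate likelihood terms are excluded; the alternative scope is a
  one-line change in `conditional_moments`).  `pD` uses the plug-in
  posterior-mean definition by default (`half_var` available); the plug-in
  evaluates the conditional law at the posterior mean of every parameter and
  latent value.  Means are arithmetic, including for phases — safe because
  phase posteriors are far from the wrap-around point in any fit where the
  diagnostic is meaningful.
* **Cross-validation**: split at `floor(2T/3)` days, fit on the head,
  forecast the tail from covariates only, RMSE between observed tail days
  and the posterior-mean (or median) prediction.
* **Six-month discrepancies**: per window, the posterior of replicated minus
  observed six-month mean WT over the window's observed days.

## Synthetic data

The generator runs the model forward with known parameters and is the test
bed for recovery, calibration and cross-validation experiments.  Defaults
emulate a 13-year medium-sized temperate river record: WT mean 12.88 °C, AT
mean 12.39 °C (amplitude ≈ 6.5 °C, phase peaking in late July), discharge
mean ≈ 5 m³/s antiphased with temperature, AR(1) daily residuals
(rho_AT = 0.8, sigma_AT = 1.2 °C; rho_Q = 0.9, sigma_Q = 0.15 log-units),
extrema-regression noise of 0.5 °C, link gains delta = 0.6 and gamma = 0.5
with sigma_zeta = 0.5 °C, and 26.98 % of WT days missing in geometric gaps of
mean length 30 days (0.63 % / 1.05 % for AT / Q).  Between-window variation
of means and amplitudes is independent Gaussian around the scenario means
(optionally with a linear trend); no explicit between-window model is implied
by the source description, and independent variation is the least-structured
choice a recovery test can use.

What the generator does **not** emulate: real rivers have heteroscedastic
and skewed residuals, ice-covered winters, flow regimes with flood spikes
rather than log-AR(1) dynamics, and sensor drift.  Passing recovery and
calibration tests therefore demonstrates internal consistency of model plus
sampler, not that the model is adequate for any particular river.

## Numerical choices and limitations

* Truncated-Normal draws use the inverse-CDF with probabilities clipped to
  [1e-14, 1−1e-14]; slice sampling caps stepping-out/shrinkage iterations
  and keeps the current point if the slice degenerates numerically.
* Simulated WT extrema pairs violating `max >= min` are redrawn (with a
  warning); with the default scenario the violation probability is
  negligible.
* Non-positive discharge is shifted to a configurable epsilon
  (0.001 m³ s⁻¹) before the log transform, with a warning.
* Acceptance and test experiments are run at desk scale (two-to-four-year
  series, desk MCMC preset, 20 replicates) — the scale at which a full
  recovery study is an interactive computation; the reference preset is
  available for production fits.
* The `fit` contract requires at least two full half-year windows where WT
  and covariates overlap; phases are only identified when windows see a
  substantial part of the annual cycle.
* Known limitations: single station per river (no spatial hierarchy), no
  riparian-shading covariate, daily time step only, and the M1 forecast
  reverts to the seasonal mean a few weeks past the training period by
  construction.
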