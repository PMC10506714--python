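# streamtemp

Hierarchical Bayesian reconstruction and forecasting of daily stream water
temperature from air temperature and (optionally) river discharge.

Stream ecologists routinely face water-temperature (WT) records that are
short and full of gaps, while air temperature (AT) and discharge (Q) are far
better observed and AT is a standard output of climate models.  `streamtemp`
fills, hindcasts and forecasts daily WT from those covariates, with full
propagation of uncertainty, and projects how much a river would warm under a
given AT warming.

## Model

Every series is decomposed into an annual sinusoid with six-month-window
means and amplitudes plus daily residuals,

```
X[y,t] = alpha_y + beta_y * sin(2*pi/n * (t - t0)) + eps[t],
```

with AR(1) residuals for the covariates.  The WT component is tied to the
covariates on two time scales:

* **seasonal** — the WT window extrema `max_y = alpha_y + beta_y`,
  `min_y = alpha_y - beta_y` are regressed on the covariate extrema,
  `E[max_y^WT] = theta0 + theta1*max_y^AT + theta2*min_y^Q` (and the mirror
  equation for the minima);
* **daily** (model variant M2) — WT deviations follow
  `delta*eps^AT + gamma*eps^Q*sin(2*pi/n*(t - t0 + n/2)) + zeta`, where the
  sine factor antiphases the WT seasonal cycle, so high flow cools the river
  in summer and warms it in winter.  Variant M1 instead models WT deviations
  as an AR(1) process.

The model is fitted by a conjugate-block MCMC sampler written for this
posterior; missing days in any series are sampled jointly with the
parameters, so gap filling and forecasting are posterior-predictive
inference, not post-processing.  See `docs/methods.md` for the full model,
priors, sampler and design notes.

## Worked example

The package ships a generator that simulates data with the model's exact
statistical structure, so every claim can be checked against known truth:

```python
import streamtemp as st

data, truth = st.simulate_dataset(st.SimulationScenario(years=4, seed=1))
draws, report = st.fit(data, mcmc=st.McmcConfig.desk(seed=3))

for name in ("delta", "gamma", "rho_at", "sigma_zeta"):
    lo, hi = draws.quantile(name, [0.025, 0.975])
    print(f"{name:11s} mean {draws.mean(name):6.3f}  "
          f"95% CI [{lo:6.3f}, {hi:6.3f}]  truth {truth[name]}")

print("chi2 p-value:", round(st.posterior_check(draws, seed=0), 3))
proj = st.project_warming(draws)
print(proj.table[["offset", "median", "q2_5", "q97_5"]].tail(1).round(2))
```

prints (seeds fixed):

```
delta       mean  0.596  95% CI [ 0.580,  0.612]  truth 0.6
gamma       mean  0.584  95% CI [ 0.421,  0.745]  truth 0.5
rho_at      mean  0.781  95% CI [ 0.747,  0.815]  truth 0.8
sigma_zeta  mean  0.507  95% CI [ 0.486,  0.529]  truth 0.5
chi2 p-value: 0.517
    offset  median  q2_5  q97_5
10     5.0    1.86  0.05   3.88
```

The daily gains `delta` (AT) and `gamma` (flow) are recovered tightly from
four years of daily data; the chi-square Bayesian p-value near 0.5 says
replicated data look like the observations; and a 5 °C AT warming projects to
a median WT warming of about 1.9 °C for this synthetic river, with the wide
interval showing how uncertain the seasonal-scale regression is on only
eight half-year windows (a longer record tightens it considerably).

The same workflow is available from the shell:

```sh
streamtemp simulate --years 4 --seed 1 --out river.csv
streamtemp fit --data river.csv --out fit/ --seed 3
streamtemp predict --fit fit/ --out predictions.csv
streamtemp evaluate --data river.csv --models m1,m2 --out comparison.csv
streamtemp project-warming --fit fit/ --grid 0:5:0.5 --out warming.csv
```

`evaluate` writes one row per model with RMSE (chronological 2/3–1/3
cross-validation), the chi-square p-value, deviance, pD and DIC.  To fit your
own river, provide a CSV with columns `date, wt, at` and optionally `q`
(m³/s); empty cells mark missing days.

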