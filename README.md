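# wmfpca — multipopulation mortality forecasting with weighted multivariate functional PCA

`wmfpca` models and forecasts age-specific mortality for several related
populations jointly.  Treating each year's log central death rate curve
`f_t^(i)(x)` (population `i`, age `x`) as a functional observation, it
implements three estimators of increasing structure:

* **independent** — a separate functional principal component (FPC) model per
  population: `f_t^(i)(x) ≈ μ^(i)(x) + Σ_n β_{t,n} φ_n^(i)(x)`, each score
  series extrapolated by an automatically selected ARIMA model;
* **wmfpca** — a joint multivariate FPC model.  Per-population FPC scores are
  stacked into a matrix `Ξ` and the eigenvectors `ĉ_n` of its weighted
  covariance `Ẑ` yield multivariate eigenfunctions
  `ψ̂_n^(i) = Σ_m [ĉ_n]_m^(i) φ̂_m^(i)` and scores `ρ̂ = Ξ ĉ` **shared by all
  populations**, so co-movement between populations is modelled explicitly;
* **coherent** — the decomposition
  `f_t^(i)(x) = μ(x) + η^(i)(x) + G_t(x) + Z_t^(i)(x)`
  with a common mean `μ`, fixed population deviations `η^(i)` (summing to zero
  over populations), a shared stochastic trend `G_t` modelled by univariate
  FPCA with ARIMA score dynamics, and population-specific residual processes
  `Z_t^(i)` modelled by multivariate FPCA with **stationarity-restricted,
  mean-zero ARMA** score dynamics.  Because the `Z` forecasts decay to zero,
  between-population forecast gaps converge to `η^(i) − η^(j)`: forecasts are
  *coherent* and never let sub-populations drift apart indefinitely.

All estimators support **geometric observation weights**
`w_t = κ(1−κ)^{T−t}` (normalized to sum to one) that discount old data, so a
recent change in the direction of mortality improvement is picked up faster;
`κ = 0` is the uniform-weight baseline, and `κ` can be tuned by rolling
out-of-sample RMSE.  Forecast intervals combine the sampling variance of the
weighted mean, the score-forecast variances projected through the
eigenfunctions, and the smoothing-residual noise variance.

The package also ships penalized-spline pre-smoothing with an optional
old-age monotonicity constraint, readers for the standard 1×1 mortality-rate
text format and CSV, a coherent synthetic data generator with known ground
truth, rolling-window evaluation and `κ` tuning, period life tables, and a
command line interface.

## Worked example

Two coupled synthetic populations, 60 years of curves on 21 ages; smooth,
weight recent years (`κ = 0.2`), fit the coherent model and forecast 10
years ahead:

```python
import numpy as np
from wmfpca import (
    estimate_sigma, fit_coherent, forecast_coherent, geometric_weights,
    smooth_surface, synthetic_data,
)

spec = synthetic_data.default_spec(p=2, T=60, J=21, K=2, L=1, seed=7)
surfaces, truth = synthetic_data.generate(spec)

scheme = geometric_weights(60, kappa=0.2)
curvesets = [
    estimate_sigma(s, smooth_surface(s, pivot_age=100), scheme)
    for s in surfaces
]

decomp = fit_coherent(curvesets, kappa=0.2)
print("common components:", decomp.common.N,
      "deviation components:", decomp.deviation.N)
print("variance explained (common):", np.round(decomp.common.explained, 4))
print("eta gap at age 10:",
      round(float(decomp.eta[0, 10] - decomp.eta[1, 10]), 4))

forecasts = forecast_coherent(decomp, h=10, alpha=0.05)
fc = forecasts[0]
print("10-year-ahead log rate at age 10:", round(float(fc.point[-1, 10]), 4))
print("95% interval:", np.round([fc.lower[-1, 10], fc.upper[-1, 10]], 4))
```

Output:

```
common components: 1 deviation components: 4
variance explained (common): [0.9785]
eta gap at age 10: 0.1783
10-year-ahead log rate at age 10: -6.0016
95% interval: [-6.1824 -5.8208]
```

The single common component carries 97.9% of the total-trend variance; the
fixed deviation functions `η̂^(i)` capture the persistent level gap between
the populations (0.178 on the log scale at age 10), which is also the limit
of the forecast gap at long horizons.

### Command line

The same pipeline from the shell:

```sh
wmfpca simulate --p 2 --years 60 --ages 0:20 --seed 7 --out demo
wmfpca forecast demo/pop1.csv demo/pop2.csv \
    --model coherent --kappa 0.2 --h 10 --pivot-age 100 --out forecasts.csv
head -3 forecasts.csv
```

```
population,year,age,point,variance,lower,upper
pop1,61,0,-2.129025046,0.01610339257,-2.377742797,-1.880307296
pop1,61,1,-2.976976481,0.005186236185,-3.118124321,-2.835828641
```

`wmfpca ingest` converts raw 1×1 mortality-rate text files or CSVs into the
package's CSV dialect, `wmfpca evaluate` computes rolling out-of-sample RMSE
per horizon (optionally tuning `κ` on a grid), and `wmfpca run` drives
ingest → smooth → fit → forecast from a flat `key=value` config file.

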