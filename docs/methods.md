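# Methods

This document records the statistical model, the estimation pipeline, the
numerical choices and their rationale, and the known limitations of the
package.

## Data model and assumptions

Observations are log central death rates `y_t^(i)(x_j)` for populations
`i = 1..p`, years `t = 1..T` and ages `x_1 < … < x_J` on a common grid.  The
observed rate is treated as a smooth underlying curve plus noise:

    y_t^(i)(x_j) = f_t^(i)(x_j) + ε_{t,j}^(i),   ε ~ independent, mean zero,
                                                  age-specific variance σ²_i(x_j)

Assumptions shared by all estimators:

* all populations share the same age grid and the same consecutive run of
  years;
* curves are smooth in age, so a penalized-spline fit of each year's
  cross-section recovers `f_t^(i)` well;
* score series are long enough for time-series model selection (at least 10
  years; in practice several decades).

### Independent model

Per population, functional PCA of the centered smoothed curves:

    f_t^(i)(x) ≈ μ^(i)(x) + Σ_{n≤N} β_{t,n} φ_n^(i)(x)

with each score series `β_{·,n}` extrapolated by an automatically selected
ARIMA model.  Populations share nothing.

### Weighted multivariate model (wMFPCA)

Univariate FPCA is run per population with all its scores collected into a
joint matrix `Ξ` (T × pN).  The weighted covariance of the joint scores,

    Ẑ = Ξᵀ diag(w) Ξ · T/(T−1),

is eigendecomposed; eigenvector `ĉ_n` maps to multivariate eigenfunctions
`ψ̂_n^(i) = Σ_m [ĉ_n]_m^(i) φ̂_m^(i)` and a single shared score series
`ρ̂_{·,n} = Ξ ĉ_n`, so all populations are driven by common factors and
cross-population covariance is modelled explicitly.

### Coherent model

    f_t^(i)(x) = μ(x) + η^(i)(x) + G_t(x) + Z_t^(i)(x),   Σ_i η^(i) = 0

estimated in six steps: (1) the cross-population average curve per year
(total function `g_t`); (2) its weighted mean `μ̂`; (3) univariate FPCA of the
centered total functions giving the common trend components and scores
`β̂`; (4) the fitted total function `g̃_t`; (5) residual deviations
`d̂_t^(i) = f̂_t^(i) − g̃_t` whose weighted means are `η̂^(i)`; (6)
multivariate FPCA of the centered deviations giving deviation scores `γ̂`.
Common scores are extrapolated by unrestricted ARIMA; deviation scores are
demeaned and extrapolated by stationarity-restricted ARMA **without a
constant**, so their forecasts decay to zero and the forecast gap between two
populations converges to `η̂^(i) − η̂^(j)` — the coherence property.

### Geometric weighting

All means, covariances and FPCAs accept geometric observation weights
`w_t ∝ κ(1−κ)^{T−t}` normalized to sum to one; `κ = 0` denotes uniform
weights.  Rows are scaled by `sqrt(w_t)` inside the covariance estimation,
while **scores are always projections of the unweighted centered curves**
onto the eigenfunctions — this keeps the score series an actual time series
of the data, and makes the weighted correlation between score columns exactly
zero.  Weighting helps when the covariance structure drifts (e.g. the
direction of mortality improvement changes late in the sample): discounting
old years rotates the leading eigenspace toward the recent regime.

## Estimation details and numerical choices

### Pre-smoothing

Each year's cross-section is fitted by clamped cubic B-splines with one
interior knot per 5 ages — enough flexibility for mortality age profiles
without chasing noise.  The roughness penalty is the sum of squared **second
differences of the fitted values** at the observed ages (rather than of the
spline coefficients): this makes the `α → ∞` limit exactly the least-squares
line, keeps fitted roughness monotone in `α`, and avoids the boundary bias a
coefficient-difference penalty inherits from the clamped basis.  `α` is
chosen by generalized cross-validation over a fixed grid
`logspace(−8, 4, 25)`; the wide lower end lets effectively-exact data (e.g.
noiseless linear curves) be reproduced to machine precision.  Above a pivot
age (default 65) the fit can be projected to be non-decreasing via isotonic
regression, reflecting that old-age mortality increases with age; pass a
pivot beyond the age range to disable the constraint (synthetic curves are
not monotone).

Noise variances are estimated from smoothing residuals pooled over years,
with a leverage correction `r²/clip(1 − h, 0.02, 1)` (`h` = hat-matrix
diagonal) so that the flexibility spent at each age does not bias σ̂²
downward; the clip guards near-interpolating fits.  The sampling variance of
the weighted mean is `τ̂²(x) = (Σ_t w_t²) σ̂²(x)`.

### FPCA numerics

Covariance operators are discretized on the age grid and eigendecomposed as
`eigh(K·Δx)`; eigenvectors are rescaled by `1/sqrt(Δx)` so eigenfunctions are
orthonormal under quadrature.  Signs are fixed deterministically (positive
integral, falling back to a positive largest-magnitude value).  The number of
components is the smallest `N` whose cumulative eigenvalue share reaches
`P = 0.9` (with `1e−12` slack against rounding); an all-zero spectrum (e.g.
identical populations leaving no deviation variance) falls back to a single
zero component rather than erroring.  Full-rank fits reproduce the input
curves to machine precision, and truncation error is non-increasing in the
retained components **in the weighted integrated-squared-error norm** the
components optimize; the max-abs error is not guaranteed monotone and small
local increases are normal.

### Score forecasting

Order selection is an exhaustive grid search (deterministic, unlike stepwise
heuristics) over `p ≤ 5, d ≤ 2, q ≤ 5` by default, compared by AIC (or BIC);
ties break toward the smaller order because candidates are visited in
lexicographic order and only strict improvement replaces the incumbent.  A
constant is fitted for `d = 0` and a drift for `d = 1`.  Exactly constant and
exactly linear series short-circuit the search (their Gaussian likelihood is
singular) and are continued deterministically.  The stationary variant
restricts to `d = 0` with stationarity enforced in estimation; with the
constant suppressed on a demeaned series its forecasts converge to exactly
zero.  Forecast means and variances are the analytic state-space quantities
from the fitted model.

### Forecast variance and intervals

The reported variance is the exact sum of its stored addends: the weighted
mean's sampling variance, each score-forecast variance times the squared
eigenfunction (common and deviation parts separately in the coherent model),
and the observation-noise variance.  Intervals are symmetric normal:
`point ± z_{α/2} sqrt(Var)`.  Parameter-estimation uncertainty of the ARIMA
coefficients beyond the state-space forecast variance is not propagated; the
empirical 95% coverage on generator replicates is about 93%.

### Evaluation

The headline accuracy metric takes the RMSE over ages per population first
and then averages over populations.  Rolling evaluation refits the model on
expanding windows, scores the h-step-ahead forecast of each window against
the observed (unsmoothed) rates, and pools squared errors over windows and
ages.  `tune_kappa` minimizes this average over a `κ` grid, breaking ties
toward smaller `κ` (less discounting unless the data demand it).

### Life table

Period life expectancy uses `q_x = m_x/(1 + 0.5 m_x)` capped at 1 (deaths
mid-interval on average, `a_x = 0.5`) and an open-ended last age group with
person-years `L_A = l_A/m_A`; then `e_x = Σ_{y ≥ x} L_y / l_x`.

## Synthetic data generator

`synthetic_data.generate` draws from the coherent model itself: a smooth
common mean with a young-age bump and old-age rise, zero-sum fixed deviations
`η^(i)`, orthonormal smooth common components driven by random-walk-with-
drift scores (sample-demeaned so the mean is identified), orthonormal
zero-sum deviation components driven by stationary AR(1) scores, plus i.i.d.
Gaussian noise.  Defaults: drifts cycling through (−0.20, 0.08, −0.05, 0.03)
with innovation sds (0.15, 0.10, 0.08, 0.06) — a dominant downward trend plus
weaker secondary movements; AR coefficient 0.6 and innovation sd 0.2 —
persistent but clearly mean-reverting deviations; noise sd 0.05 — comparable
to observed log-rate sampling noise at moderate exposures.
`trend_break_surfaces` generates a regime change where the break alters
*which* shape direction is improving, the situation geometric weighting is
designed for.

What it emulates: smooth age profiles, a common stochastic trend, persistent
but stationary population gaps, trend breaks, measurement noise, missing
cells.  What it does not emulate: cohort effects, death-count (Poisson)
heteroscedasticity, mortality shocks such as pandemics or wars, jump-off
bias, or realistic old-age levels — its old-age rates are lighter than human
mortality, so synthetic life expectancies (110+ on a 0–100 grid) exceed
realistic values; the life-table code itself is exact for the rates given.

## Problem sizes

The test and demonstration sizes are the package's own choices, picked to
give stable statistics on a single CPU in minutes: decomposition checks at
p=2, T=60, J=21; parameter recovery at T=200 with noise sd 0.01; interval
calibration over 500 generator replicates (100 in the acceptance script) at
horizons 1–10; `κ`-tuning behaviour over 50 replicates (10 in the script).

## Open design decisions and limitations

* Geometric weights underflow in float64 for extreme `κ` with long samples
  (e.g. `κ > 0.95` with `T ≥ 200` drives early weights to zero exactly);
  practical tuning grids stay well below that.
* Automatic component selection can merge highly sample-correlated
  random-walk components into one; when the true dimension is known (as in
  simulation studies) pass `K`/`L` explicitly.
* Spline fits carry mild extra bias at the first/last one or two ages, which
  inflates the estimated noise sd there slightly.
* Interval calibration is evaluated under the generator's own model;
  real-data coverage will degrade under model misspecification.
* Smoothing residuals are treated as independent across ages when pooling
  the noise variance.
* The CLI's `run` config is intentionally a flat `key=value` file; anything
  richer should use the Python API.
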