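"""The three mortality forecasting estimators.

* **independent FPCA** — one univariate FPCA per population, each forecast on
  its own (the classical functional data baseline; populations share nothing,
  so long-run forecasts may diverge);
* **wMFPCA** — a joint multivariate FPCA of all populations with
  geometrically decaying observation weights; scores are shared across
  populations but extrapolated by possibly non-stationary ARIMA, so forecasts
  may still diverge;
* **coherent wMFPCA** — decomposes each population's smoothed log mortality
  into grand mean + fixed population deviation + common trend + stationary
  population deviation trend:

      f_t^(i)(x) = mu(x) + eta^(i)(x) + G_t(x) + Z_t^(i)(x).

  The common-trend scores may be non-stationary (ARIMA), while the deviation
  scores are demeaned and extrapolated by stationarity-restricted ARMA whose
  forecasts converge to zero.  Between-population forecast gaps therefore
  converge to the fixed gaps ``eta^(i) - eta^(j)``: the forecasts are
  *coherent*.

Forecast variance is the sum of independent-term variances: sampling variance
of the smoothed mean estimate, score-forecast variances scaled by squared
eigenfunctions, and the observation-noise variance.  Prediction intervals are
symmetric normal: point ± z_alpha * sqrt(variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .fpca import MultivariateFPCA, UnivariateFPCA, mfpca_from_ufpca, ufpca, ufpca_matrix
from .smoothing import SmoothCurveSet
from .ts_forecast import forecast_score_arima, forecast_score_stationary
from .weighting import WeightScheme, geometric_weights, weighted_mean_curve

__all__ = [
    "WMFPCAModel",
    "IndependentModel",
    "CoherentDecomposition",
    "MortalityForecast",
    "fit_wmfpca",
    "forecast_wmfpca",
    "fit_coherent",
    "forecast_coherent",
    "fit_independent",
    "forecast_independent",
]


@dataclass
class MortalityForecast:
    """h-step forecasts of log mortality for one population."""

    population_id: str
    horizon: int
    ages: np.ndarray
    point: np.ndarray  # (h, J)
    variance: np.ndarray  # (h, J)
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    z_alpha: float
    components: dict = field(default_factory=dict)  # named variance addends

    def __post_init__(self) -> None:
        if np.any(self.variance < 0):
            raise ValueError("forecast variance must be non-negative")


def _check_common_grid(curvesets: list) -> None:
    ref = curvesets[0]
    for cs in curvesets[1:]:
        if not np.array_equal(cs.ages, ref.ages) or not np.array_equal(cs.years, ref.years):
            raise ValueError("curve sets must share the same age grid and year range")


def _noise_terms(curvesets: list, scheme: WeightScheme):
    """Per-population observation variance profile and mean-estimate variance."""
    sigma2 = np.array([cs.sigma[0] ** 2 for cs in curvesets])
    mean_var = (scheme.weights**2).sum() * sigma2
    return sigma2, mean_var


def _interval(point, variance, alpha):
    z = float(norm.ppf(1.0 - alpha / 2.0))
    half = z * np.sqrt(variance)
    return point - half, point + half, z


# ---------------------------------------------------------------------------
# wMFPCA
# ---------------------------------------------------------------------------


@dataclass
class WMFPCAModel:
    """Fitted weighted multivariate FPCA model (kappa = 0: unweighted MFPCA)."""

    mfpca: MultivariateFPCA
    scheme: WeightScheme
    kappa: float
    P: float
    sigma2: np.ndarray  # (p, J)
    mean_var: np.ndarray  # (p, J)
    population_ids: list

    @property
    def p(self) -> int:
        return self.mfpca.p


def fit_wmfpca(
    curvesets: list,
    kappa: float,
    P: float = 0.9,
    n_components: int | str | None = None,
    uni_components: int | str | None = None,
) -> WMFPCAModel:
    """Fit the wMFPCA model to p smoothed curve sets on a common grid."""
    _check_common_grid(curvesets)
    T = curvesets[0].n_years
    scheme = geometric_weights(T, kappa)
    fits = [ufpca(cs, scheme, P=P, n_components=uni_components) for cs in curvesets]
    mf = mfpca_from_ufpca(fits, P=P, n_components=n_components)
    sigma2, mean_var = _noise_terms(curvesets, scheme)
    return WMFPCAModel(
        mfpca=mf,
        scheme=scheme,
        kappa=kappa,
        P=P,
        sigma2=sigma2,
        mean_var=mean_var,
        population_ids=[cs.population_id for cs in curvesets],
    )


def forecast_wmfpca(
    model: WMFPCAModel,
    h: int,
    alpha: float = 0.05,
    criterion: str = "aic",
    max_order: tuple = (5, 2, 5),
) -> list:
    """Forecast every population h steps ahead with prediction intervals."""
    if h < 1:
        raise ValueError("horizon must be at least 1")
    mf = model.mfpca
    score_fc = [
        forecast_score_arima(mf.mv_scores[:, n], h, criterion=criterion, max_order=max_order)
        for n in range(mf.N)
    ]
    ages = mf.uni_fits[0].ages
    out = []
    for i, fit in enumerate(mf.uni_fits):
        psi = mf.mv_eigenfunctions[i]  # (N, J)
        point = fit.mean[None, :] + sum(
            np.outer(score_fc[n].point, psi[n]) for n in range(mf.N)
        )
        score_var = sum(np.outer(score_fc[n].variance, psi[n] ** 2) for n in range(mf.N))
        variance = model.mean_var[i][None, :] + score_var + model.sigma2[i][None, :]
        lower, upper, z = _interval(point, variance, alpha)
        out.append(
            MortalityForecast(
                population_id=model.population_ids[i],
                horizon=h,
                ages=ages,
                point=point,
                variance=variance,
                lower=lower,
                upper=upper,
                alpha=alpha,
                z_alpha=z,
                components={
                    "mean_var": np.broadcast_to(model.mean_var[i], point.shape).copy(),
                    "score_var": np.asarray(score_var) + np.zeros_like(point),
                    "obs_var": np.broadcast_to(model.sigma2[i], point.shape).copy(),
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# independent FPCA baseline
# ---------------------------------------------------------------------------


@dataclass
class IndependentModel:
    """Univariate FPCA fit of a single population."""

    fit: UnivariateFPCA
    scheme: WeightScheme
    kappa: float
    P: float
    sigma2: np.ndarray  # (J,)
    mean_var: np.ndarray  # (J,)


def fit_independent(
    curveset: SmoothCurveSet,
    kappa: float = 0.0,
    P: float = 0.9,
    n_components: int | str | None = None,
) -> IndependentModel:
    """Fit one population on its own (no information shared across populations)."""
    T = curveset.n_years
    scheme = geometric_weights(T, kappa)
    fit = ufpca(curveset, scheme, P=P, n_components=n_components)
    sigma2 = curveset.sigma[0] ** 2
    mean_var = (scheme.weights**2).sum() * sigma2
    return IndependentModel(fit, scheme, kappa, P, sigma2, mean_var)


def forecast_independent(
    model: IndependentModel,
    h: int,
    alpha: float = 0.05,
    criterion: str = "aic",
    max_order: tuple = (5, 2, 5),
) -> MortalityForecast:
    if h < 1:
        raise ValueError("horizon must be at least 1")
    fit = model.fit
    score_fc = [
        forecast_score_arima(fit.scores[:, n], h, criterion=criterion, max_order=max_order)
        for n in range(fit.N)
    ]
    point = fit.mean[None, :] + sum(
        np.outer(score_fc[n].point, fit.eigenfunctions[n]) for n in range(fit.N)
    )
    score_var = sum(
        np.outer(score_fc[n].variance, fit.eigenfunctions[n] ** 2) for n in range(fit.N)
    )
    variance = model.mean_var[None, :] + score_var + model.sigma2[None, :]
    lower, upper, z = _interval(point, variance, alpha)
    return MortalityForecast(
        population_id=fit.population_id,
        horizon=h,
        ages=fit.ages,
        point=point,
        variance=variance,
        lower=lower,
        upper=upper,
        alpha=alpha,
        z_alpha=z,
        components={
            "mean_var": np.broadcast_to(model.mean_var, point.shape).copy(),
            "score_var": np.asarray(score_var) + np.zeros_like(point),
            "obs_var": np.broadcast_to(model.sigma2, point.shape).copy(),
        },
    )


# ---------------------------------------------------------------------------
# coherent wMFPCA
# ---------------------------------------------------------------------------


@dataclass
class CoherentDecomposition:
    """Fitted coherent decomposition mu + eta^(i) + G_t + Z_t^(i)."""

    mu: np.ndarray  # (J,)
    eta: np.ndarray  # (p, J)
    common: UnivariateFPCA  # FPCA of the centered total function (K comps)
    deviation: MultivariateFPCA  # MFPCA of the centered deviations (L comps)
    totals: np.ndarray  # (T, J) fitted weighted total function g~_t
    deviations_raw: np.ndarray  # (p, T, J) d^(i)_t
    scheme: WeightScheme
    kappa: float
    P: float
    sigma2: np.ndarray  # (p, J)
    mean_var: np.ndarray  # (p, J)
    population_ids: list
    ages: np.ndarray

    @property
    def p(self) -> int:
        return len(self.population_ids)

    @property
    def K(self) -> int:
        return self.common.N

    @property
    def L(self) -> int:
        return self.deviation.N

    def population_mean(self, i: int) -> np.ndarray:
        """mu^(i) = mu + eta^(i)."""
        return self.mu + self.eta[i]


def fit_coherent(
    curvesets: list,
    kappa: float,
    P: float = 0.9,
    K: int | str | None = None,
    L: int | str | None = None,
    uni_components: int | str | None = None,
) -> CoherentDecomposition:
    """Estimate the coherent decomposition in six steps.

    1. total function ``g_t = (1/p) sum_i f_t^(i)``, weighted mean ``mu``;
    2. center ``g`` and apply the observation weights;
    3. univariate FPCA of the centered total -> K common components and the
       fitted total ``g~_t = mu + sum_k beta_{t,k} phi_k``;
    4. deviations ``d_t^(i) = f_t^(i) - g~_t``, weighted means ``eta^(i)``;
    5. center and weight the deviations;
    6. multivariate FPCA of the deviations -> L components with scores shared
       across populations.

    ``K``, ``L`` and ``uni_components`` override the cumulative-variance rule
    (``"all"`` keeps every component, giving an exact in-sample identity).
    """
    _check_common_grid(curvesets)
    T = curvesets[0].n_years
    ages = curvesets[0].ages
    scheme = geometric_weights(T, kappa)

    f = np.array([cs.curves for cs in curvesets])  # (p, T, J)
    g = f.mean(axis=0)  # step 1: equal average across populations
    common = ufpca_matrix(g, ages, scheme, P=P, n_components=K, population_id="total")
    totals = common.mean[None, :] + common.scores @ common.eigenfunctions  # g~_t

    d = f - totals[None, :, :]  # step 4
    dev_fits = [
        ufpca_matrix(
            d[i], ages, scheme, P=P, n_components=uni_components,
            population_id=curvesets[i].population_id,
        )
        for i in range(len(curvesets))
    ]
    deviation = mfpca_from_ufpca(dev_fits, P=P, n_components=L)

    eta = np.array([fit.mean for fit in dev_fits])
    sigma2, mean_var = _noise_terms(curvesets, scheme)
    return CoherentDecomposition(
        mu=common.mean,
        eta=eta,
        common=common,
        deviation=deviation,
        totals=totals,
        deviations_raw=d,
        scheme=scheme,
        kappa=kappa,
        P=P,
        sigma2=sigma2,
        mean_var=mean_var,
        population_ids=[cs.population_id for cs in curvesets],
        ages=ages,
    )


def forecast_coherent(
    decomp: CoherentDecomposition,
    h: int,
    alpha: float = 0.05,
    criterion: str = "aic",
    max_order: tuple = (5, 2, 5),
    max_order_stationary: tuple = (5, 5),
) -> list:
    """Coherent h-step forecasts for every population.

    Common-trend scores are extrapolated by (possibly non-stationary) ARIMA;
    deviation scores are demeaned and extrapolated by stationarity-restricted
    ARMA without a constant, so their forecasts — and with them the
    population gaps net of ``eta`` — converge to zero as h grows.
    """
    if h < 1:
        raise ValueError("horizon must be at least 1")
    common, deviation = decomp.common, decomp.deviation
    beta_fc = [
        forecast_score_arima(common.scores[:, k], h, criterion=criterion, max_order=max_order)
        for k in range(common.N)
    ]
    gamma_fc = []
    for l in range(deviation.N):
        series = deviation.mv_scores[:, l]
        gamma_fc.append(
            forecast_score_stationary(
                series - series.mean(), h, criterion=criterion,
                max_order=max_order_stationary, include_mean=False,
            )
        )

    common_point = sum(
        np.outer(beta_fc[k].point, common.eigenfunctions[k]) for k in range(common.N)
    )
    common_var = sum(
        np.outer(beta_fc[k].variance, common.eigenfunctions[k] ** 2)
        for k in range(common.N)
    )

    out = []
    for i in range(decomp.p):
        phi_i = deviation.mv_eigenfunctions[i]  # (L, J)
        dev_point = sum(np.outer(gamma_fc[l].point, phi_i[l]) for l in range(deviation.N))
        dev_var = sum(np.outer(gamma_fc[l].variance, phi_i[l] ** 2) for l in range(deviation.N))
        point = decomp.population_mean(i)[None, :] + common_point + dev_point
        variance = (
            decomp.mean_var[i][None, :]
            + common_var
            + dev_var
            + decomp.sigma2[i][None, :]
        )
        lower, upper, z = _interval(point, variance, alpha)
        out.append(
            MortalityForecast(
                population_id=decomp.population_ids[i],
                horizon=h,
                ages=decomp.ages,
                point=point,
                variance=variance,
                lower=lower,
                upper=upper,
                alpha=alpha,
                z_alpha=z,
                components={
                    "mean_var": np.broadcast_to(decomp.mean_var[i], point.shape).copy(),
                    "common_var": np.asarray(common_var) + np.zeros_like(point),
                    "deviation_var": np.asarray(dev_var) + np.zeros_like(point),
                    "obs_var": np.broadcast_to(decomp.sigma2[i], point.shape).copy(),
                },
            )
        )
    return out
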