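"""Extrapolation of principal-component score series.

Two entry points share one engine:

* :func:`forecast_score_arima` — possibly non-stationary ARIMA with an
  exhaustive order search over ``p <= 5, d <= 2, q <= 5`` (the search is
  exhaustive rather than stepwise so order selection is deterministic);
  a constant is included for ``d = 0`` fits and a drift term for ``d = 1``;
* :func:`forecast_score_stationary` — the search restricted to ``d = 0``
  ARMA(p, q) with stationarity enforced in estimation, so point forecasts
  converge to the fitted process mean (or to exactly zero when the series is
  demeaned and ``include_mean=False`` — the convention used for the deviation
  scores of the coherent model, whose population mean is zero by
  construction).

Orders are compared by AIC (default) or BIC; ties break toward the smaller
total order because candidates are visited in lexicographic order and only a
strictly better criterion replaces the incumbent.  Analytic h-step forecast
means and variances come from the fitted state-space model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.arima.model import ARIMA

__all__ = ["ScoreForecast", "forecast_score_arima", "forecast_score_stationary"]

_DEGENERATE_TOL = 1e-10


@dataclass
class ScoreForecast:
    """h-step point forecasts and forecast variances of one score series."""

    horizon: int
    point: np.ndarray  # (h,)
    variance: np.ndarray  # (h,)
    order: tuple  # (p, d, q)
    criterion: float
    criterion_name: str
    stationary: bool
    params: dict = None  # type: ignore[assignment]  # fitted coefficients by name


def _trend_for(d: int, include_mean: bool) -> str:
    if not include_mean:
        return "n"
    return {0: "c", 1: "t"}.get(d, "n")


def _fit_one(series: np.ndarray, order: tuple, include_mean: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(series, order=order, trend=_trend_for(order[1], include_mean))
        return model.fit()


def _search(series: np.ndarray, h: int, criterion: str, candidates, include_mean: bool,
            stationary: bool) -> ScoreForecast:
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("score series contains non-finite values")
    if len(series) < 10:
        raise ValueError("need at least 10 observations to fit a score model")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")

    # degenerate series short-circuits: exact constants and exact lines make
    # the Gaussian likelihood singular
    if np.ptp(series) < _DEGENERATE_TOL:
        point = np.full(h, float(series[-1]))
        return ScoreForecast(h, point, np.zeros(h), (0, 0, 0), -np.inf, criterion, True, {})
    diffs = np.diff(series)
    if not stationary and np.ptp(diffs) < _DEGENERATE_TOL:
        slope = float(diffs[0])
        point = series[-1] + slope * np.arange(1, h + 1)
        return ScoreForecast(h, point, np.zeros(h), (0, 1, 0), -np.inf, criterion, False,
                             {"drift": slope})

    best = None
    for order in candidates:
        try:
            res = _fit_one(series, order, include_mean)
            value = float(getattr(res, criterion))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.isfinite(value):
            continue
        if best is None or value < best[0]:
            best = (value, order, res)
    if best is None:
        raise RuntimeError("every candidate order failed to fit")

    value, order, res = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fc = res.get_forecast(h)
        point = np.asarray(fc.predicted_mean, dtype=float)
        variance = np.asarray(fc.se_mean, dtype=float) ** 2
    variance = np.clip(variance, 0.0, None)
    params = dict(zip(res.model.param_names, np.asarray(res.params, dtype=float)))
    return ScoreForecast(h, point, variance, order, value, criterion,
                         stationary and order[1] == 0, params)


def forecast_score_arima(
    series: np.ndarray,
    h: int,
    criterion: str = "aic",
    max_order: tuple = (5, 2, 5),
    include_mean: bool = True,
) -> ScoreForecast:
    """Automatic (possibly non-stationary) ARIMA forecast of a score series.

    With ``include_mean=True`` (default) a constant is estimated for ``d = 0``
    models and a drift for ``d = 1``; ``include_mean=False`` fits the pure
    stochastic models (a ``(0,1,0)`` fit then forecasts the last observation
    at every horizon).
    """
    if h < 1:
        raise ValueError("horizon must be positive")
    p_max, d_max, q_max = max_order
    candidates = [
        (p, d, q)
        for p in range(p_max + 1)
        for d in range(d_max + 1)
        for q in range(q_max + 1)
    ]
    return _search(series, h, criterion, candidates, include_mean=include_mean,
                   stationary=False)


def forecast_score_stationary(
    series: np.ndarray,
    h: int,
    criterion: str = "aic",
    max_order: tuple = (5, 5),
    include_mean: bool = True,
) -> ScoreForecast:
    """Stationarity-restricted ARMA forecast (d = 0, AR roots outside the
    unit circle enforced in estimation).

    With ``include_mean=False`` the model has no constant, so forecasts of a
    demeaned series converge to exactly zero as ``h`` grows.
    """
    if h < 1:
        raise ValueError("horizon must be positive")
    p_max, q_max = max_order
    candidates = [(p, 0, q) for p in range(p_max + 1) for q in range(q_max + 1)]
    return _search(series, h, criterion, candidates, include_mean=include_mean,
                   stationary=True)
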