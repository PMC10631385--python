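"""Forecast-accuracy evaluation and demographic diagnostics.

The headline metric averages per-population RMSEs over ages:

    RMSE = (1/p) sum_i sqrt( (1/J) sum_j (Y^(i)(x_j) - Yhat^(i)(x_j))^2 )

(the root is taken per population before averaging).  Rolling-window
evaluation retrains the chosen model on an expanding sample, forecasts h
years ahead, and pools squared errors over windows and ages.  The decay
parameter kappa is tuned by minimizing the rolling RMSE averaged over
populations on training data.

Life expectancy uses a standard period life table: ``q_x = m_x / (1 + 0.5
m_x)`` (deaths mid-interval on average), ``a_x = 0.5``, an open-ended last
age group with ``L_A = l_A / m_A``, and ``e_x = sum_{y >= x} L_y / l_x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    fit_coherent,
    fit_independent,
    fit_wmfpca,
    forecast_coherent,
    forecast_independent,
    forecast_wmfpca,
)
from .smoothing import estimate_sigma, smooth_surface
from .weighting import geometric_weights

__all__ = [
    "EvaluationResult",
    "rmse_avg",
    "rolling_rmse",
    "tune_kappa",
    "life_expectancy",
    "sex_ratio",
]

MODEL_KINDS = ("independent", "wmfpca", "coherent")


@dataclass
class EvaluationResult:
    """Rolling-window RMSE of one model run."""

    label: str
    model_kind: str
    horizon: int
    kappa: float
    n_windows: int
    window_starts: np.ndarray  # training lengths used per window
    rmse: dict  # population_id -> rolling RMSE
    p: int
    J: int

    @property
    def average(self) -> float:
        return float(np.mean(list(self.rmse.values())))


def rmse_avg(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Average over populations of the per-population age-profile RMSE."""
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted shapes differ")
    per_pop = np.sqrt(np.mean((actual - predicted) ** 2, axis=1))
    return float(per_pop.mean())


def _forecast_last_step(model_kind, curvesets, h, kappa, P, **ts_kwargs):
    """Point forecast (p, J) for the h-th step ahead of the training sample."""
    if callable(model_kind):
        return np.asarray(model_kind(curvesets, h, kappa, P))
    if model_kind == "independent":
        preds = []
        for cs in curvesets:
            model = fit_independent(cs, kappa, P)
            preds.append(forecast_independent(model, h, **ts_kwargs).point[-1])
        return np.array(preds)
    if model_kind == "wmfpca":
        model = fit_wmfpca(curvesets, kappa, P)
        return np.array([fc.point[-1] for fc in forecast_wmfpca(model, h, **ts_kwargs)])
    if model_kind == "coherent":
        decomp = fit_coherent(curvesets, kappa, P)
        kwargs = dict(ts_kwargs)
        if "max_order" in kwargs:  # cap the ARMA search consistently
            p_max, _, q_max = kwargs["max_order"]
            kwargs.setdefault("max_order_stationary", (p_max, q_max))
        return np.array([fc.point[-1] for fc in forecast_coherent(decomp, h, **kwargs)])
    raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


def rolling_rmse(
    surfaces: list,
    model_kind,
    h: int,
    n_windows: int = 10,
    kappa: float = 0.0,
    P: float = 0.9,
    pivot_age: int = 65,
    smoothness: float | str = "auto",
    min_train: int = 10,
    **ts_kwargs,
) -> EvaluationResult:
    """Expanding-window out-of-sample RMSE per population.

    Window ``w`` trains on the first ``t0 + w`` years and scores the forecast
    of year ``t0 + w + h`` against the observed log rates; squared errors are
    pooled over all windows and ages, so each population's value is
    ``sqrt( sum_{w,j} err^2 / (n_windows * J) )``.  The model is refitted in
    every window.  ``model_kind`` is one of ``independent | wmfpca |
    coherent`` or a callable ``(train_curvesets, h, kappa, P) -> (p, J)``
    (useful for stub models in tests).

    ``ts_kwargs`` (e.g. ``max_order``) pass through to the score forecasters.
    """
    T = surfaces[0].n_years
    t0 = T - h - (n_windows - 1)
    if t0 < min_train:
        raise ValueError(
            f"insufficient years: need at least {min_train + h + n_windows - 1}, have {T}"
        )
    smoothed = [smooth_surface(s, pivot_age=pivot_age, smoothness=smoothness) for s in surfaces]
    J = surfaces[0].n_ages
    p = len(surfaces)

    sq_sum = np.zeros(p)
    counts = np.zeros(p)
    starts = []
    for w in range(n_windows):
        n_train = t0 + w
        starts.append(n_train)
        train_sets = []
        for s, cs in zip(surfaces, smoothed):
            sub = cs.subset_years(n_train)
            sub_surface = type(s)(
                s.population_id, s.ages, s.years[:n_train],
                s.log_rates[:n_train], s.missing_mask[:n_train],
            )
            train_sets.append(estimate_sigma(sub_surface, sub, geometric_weights(n_train, kappa)))
        pred = _forecast_last_step(model_kind, train_sets, h, kappa, P, **ts_kwargs)
        target = n_train + h - 1
        for i, s in enumerate(surfaces):
            use = ~s.missing_mask[target]
            err = s.log_rates[target, use] - pred[i, use]
            sq_sum[i] += float(err @ err)
            counts[i] += use.sum()

    rmse = {
        s.population_id: float(np.sqrt(sq_sum[i] / counts[i])) for i, s in enumerate(surfaces)
    }
    return EvaluationResult(
        label=",".join(s.population_id for s in surfaces),
        model_kind=model_kind if isinstance(model_kind, str) else "custom",
        horizon=h,
        kappa=kappa,
        n_windows=n_windows,
        window_starts=np.array(starts),
        rmse=rmse,
        p=p,
        J=J,
    )


def tune_kappa(
    surfaces: list,
    model_kind,
    h: int,
    grid,
    n_windows: int = 10,
    P: float = 0.9,
    **kwargs,
):
    """Pick the decay parameter minimizing rolling RMSE averaged over
    populations.

    Evaluates every grid point (no early stopping); ties break toward the
    smaller kappa.  Run this on the training span only, then forecast the
    holdout with the returned value.  Returns ``(best_kappa, profile)`` where
    ``profile`` maps each kappa to its average rolling RMSE.
    """
    grid = sorted(set(float(k) for k in grid))
    if not grid:
        raise ValueError("kappa grid must be non-empty")
    profile = {}
    best_kappa, best_value = None, np.inf
    for kappa in grid:
        result = rolling_rmse(
            surfaces, model_kind, h, n_windows=n_windows, kappa=kappa, P=P, **kwargs
        )
        profile[kappa] = result.average
        if result.average < best_value:
            best_kappa, best_value = kappa, result.average
    return best_kappa, profile


def life_expectancy(log_rate_curve: np.ndarray) -> np.ndarray:
    """Period life expectancy ``e_x`` at every age of the input curve.

    The input is a log central death rate curve on ages ``0..A``; the last
    age is treated as an open-ended group.
    """
    log_m = np.asarray(log_rate_curve, dtype=float)
    if not np.all(np.isfinite(log_m)):
        raise ValueError("log rate curve must be finite")
    m = np.exp(log_m)
    if np.any(m <= 0):
        raise ValueError("death rates must be positive")
    A = len(m)
    q = np.minimum(m / (1.0 + 0.5 * m), 1.0)

    l = np.empty(A)
    l[0] = 1.0
    for x in range(1, A):
        l[x] = l[x - 1] * (1.0 - q[x - 1])
    d = l * q
    L = l - 0.5 * d
    L[-1] = l[-1] / m[-1]  # open-ended last age group
    total = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, total / np.where(l > 0, l, 1.0), 0.0)
    return e


def sex_ratio(log_rates_a: np.ndarray, log_rates_b: np.ndarray) -> np.ndarray:
    """Elementwise rate ratio exp(A - B), e.g. male/female mortality ratio."""
    a = np.asarray(log_rates_a, dtype=float)
    b = np.asarray(log_rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must have the same shape")
    return np.exp(a - b)
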