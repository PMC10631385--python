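"""Per-year smoothing of log mortality curves.

Each year's observed log rates are fitted with a penalized cubic B-spline on
the age grid (one interior knot per five years of age).  The penalty is on
the second differences of the *fitted values* over the age grid, so straight
lines are reproduced exactly at any penalty weight and the fitted curve's
roughness is non-increasing in the weight.  The weight is either fixed or
chosen per curve by generalized cross-validation.  Because adult mortality
increases with age, the fitted curve is then projected onto the monotone cone
above a pivot age (default 65) with isotonic regression
(pool-adjacent-violators), which is deterministic and leaves the fit below
the pivot untouched.

Masked cells are simply excluded from the fit and filled with the spline
prediction.  The observation-noise scale ``sigma(x)`` is estimated afterwards
by pooling leverage-corrected squared residuals over years at each age
(dividing by ``1 - h_jj`` removes the downward bias of raw residuals where
the smoother has high leverage, notably at the boundary ages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from sklearn.isotonic import isotonic_regression

from .io_hmd import MortalitySurface
from .weighting import WeightScheme

__all__ = ["SmoothCurveSet", "smooth_surface", "estimate_sigma"]


@dataclass
class SmoothCurveSet:
    """Smoothed curves f̂_t(x_j) with per-age noise scales.

    ``sigma`` holds the estimated observation-noise standard deviation (log
    rate units) replicated across years; ``mean_var`` the pointwise sampling
    variance of the (weighted) mean curve estimate.  Both are zero until
    :func:`estimate_sigma` runs.
    """

    population_id: str
    ages: np.ndarray
    years: np.ndarray
    curves: np.ndarray  # (T, J)
    sigma: np.ndarray = field(default=None)  # type: ignore[assignment]
    mean_var: np.ndarray = field(default=None)  # type: ignore[assignment]
    leverage: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.curves = np.asarray(self.curves, dtype=float)
        T, J = self.curves.shape
        if self.sigma is None:
            self.sigma = np.zeros((T, J))
        if self.mean_var is None:
            self.mean_var = np.zeros(J)
        if self.leverage is None:
            self.leverage = np.zeros((T, J))
        if not np.all(np.isfinite(self.curves)):
            raise ValueError("smoothed curves must be finite everywhere")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    def subset_years(self, n_first: int) -> "SmoothCurveSet":
        """First ``n_first`` years (smoothing is per-year, so this equals
        re-smoothing the truncated surface)."""
        return SmoothCurveSet(
            self.population_id,
            self.ages,
            self.years[:n_first],
            self.curves[:n_first].copy(),
            self.sigma[:n_first].copy(),
            self.mean_var.copy(),
            self.leverage[:n_first].copy(),
        )


def _spline_design(ages: np.ndarray, knot_every: float = 5.0):
    """Clamped cubic B-spline design matrix with one knot per ``knot_every``
    years of age."""
    x = np.asarray(ages, dtype=float)
    a, b = x[0], x[-1]
    interior = np.arange(a + knot_every, b, knot_every)
    knots = np.concatenate([[a] * 4, interior, [b] * 4])
    design = BSpline.design_matrix(x, knots, 3).toarray()
    return design, knots


def _second_diff_penalty(design: np.ndarray) -> np.ndarray:
    """Penalty on second differences of the fitted values B @ c."""
    DB = np.diff(design, n=2, axis=0)
    return DB.T @ DB


def _gcv_alpha(B: np.ndarray, y: np.ndarray, P: np.ndarray) -> float:
    """Generalized cross-validation over a fixed log-spaced penalty grid."""
    n = len(y)
    BtB, Bty = B.T @ B, B.T @ y
    best_alpha, best_score = None, np.inf
    for alpha in np.logspace(-8.0, 4.0, 25):
        A = BtB + alpha * P
        try:
            coef = np.linalg.solve(A, Bty)
            trace_H = np.trace(np.linalg.solve(A, BtB))
        except np.linalg.LinAlgError:
            continue
        resid = y - B @ coef
        denom = max(n - trace_H, 1e-8)
        score = n * float(resid @ resid) / denom**2
        if score < best_score:
            best_score, best_alpha = score, alpha
    if best_alpha is None:
        raise ValueError("GCV failed at every penalty value")
    return best_alpha


def smooth_surface(
    surface: MortalitySurface,
    pivot_age: int = 65,
    smoothness: float | str = "auto",
) -> SmoothCurveSet:
    """Smooth every year of a surface; enforce monotone rates above
    ``pivot_age``.

    ``smoothness`` is the penalty weight, or ``"auto"`` for per-curve GCV.
    Raises if any year has fewer usable cells than spline coefficients.
    """
    design, _ = _spline_design(surface.ages)
    n_coef = design.shape[1]
    P = _second_diff_penalty(design)
    above = surface.ages >= pivot_age

    curves = np.empty((surface.n_years, surface.n_ages))
    leverage = np.zeros((surface.n_years, surface.n_ages))
    for t in range(surface.n_years):
        keep = ~surface.missing_mask[t]
        if keep.sum() < n_coef:
            raise ValueError(
                f"year {surface.years[t]}: {int(keep.sum())} usable cells "
                f"< {n_coef} spline coefficients"
            )
        B, y = design[keep], surface.log_rates[t, keep]
        alpha = _gcv_alpha(B, y, P) if smoothness == "auto" else float(smoothness)
        A = B.T @ B + alpha * P
        coef = np.linalg.solve(A, B.T @ y)
        fitted = design @ coef
        leverage[t, keep] = np.einsum("ij,ij->i", B, np.linalg.solve(A, B.T).T)
        if above.sum() >= 2:
            fitted[above] = isotonic_regression(fitted[above], increasing=True)
        curves[t] = fitted

    return SmoothCurveSet(surface.population_id, surface.ages, surface.years, curves,
                          leverage=leverage)


def estimate_sigma(
    surface: MortalitySurface,
    curveset: SmoothCurveSet,
    scheme: WeightScheme | None = None,
) -> SmoothCurveSet:
    """Pool residual variance over years at each age.

    The per-age leverage-corrected root-mean-square residual is replicated
    across years as the noise scale ``sigma`` (the age profile is estimable
    from the data, a year-by-year noise scale is not).  ``mean_var`` is the
    sampling variance of the weighted mean curve, ``sum_t w_t^2 *
    sigma^2(x)``; with uniform weights this is the familiar ``sigma^2 / T``.
    """
    resid = surface.log_rates - curveset.curves
    denom = np.clip(1.0 - curveset.leverage, 0.02, 1.0)
    scaled = np.where(surface.missing_mask, np.nan, resid**2 / denom)
    with np.errstate(invalid="ignore"):
        pooled_var = np.nanmean(scaled, axis=0)
    pooled_var = np.where(np.isfinite(pooled_var), pooled_var, 0.0)
    sigma_age = np.sqrt(pooled_var)

    T = curveset.n_years
    w = scheme.weights if scheme is not None else np.full(T, 1.0 / T)
    mean_var = (w**2).sum() * pooled_var
    return SmoothCurveSet(
        curveset.population_id,
        curveset.ages,
        curveset.years,
        curveset.curves.copy(),
        np.tile(sigma_age, (T, 1)),
        mean_var,
        curveset.leverage.copy(),
    )
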