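"""Geometrically decaying observation weights.

Recent mortality experience is usually more informative about the future than
the distant past.  The weight given to the curve observed in year ``t`` (out
of ``T``) is ``w_t = kappa * (1 - kappa)^(T - t)`` with ``0 < kappa < 1``, so
weights decay geometrically backwards in time.  ``kappa = 0`` is the uniform
sentinel (ordinary, unweighted estimation).

The raw weights sum to ``1 - (1 - kappa)^T < 1``; we normalize them to sum to
one so the weighted mean is a proper average.  Normalization rescales the
weighted covariance by a constant and therefore leaves eigenfunctions, scores
and every forecast invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeightScheme", "geometric_weights", "weighted_mean_curve", "weight_rows_for_eigen"]


@dataclass(frozen=True)
class WeightScheme:
    """Normalized geometric observation weights for ``T`` curves."""

    kappa: float
    raw_weights: np.ndarray
    weights: np.ndarray

    @property
    def T(self) -> int:
        return len(self.weights)


def geometric_weights(T: int, kappa: float) -> WeightScheme:
    """Build the weight scheme ``w_t ∝ kappa (1-kappa)^(T-t)``.

    Parameters
    ----------
    T:
        Number of observed years, at least 2.
    kappa:
        Decay parameter in ``[0, 1)``; ``0`` means uniform weights.
    """
    if not 0.0 <= kappa < 1.0:
        raise ValueError(f"kappa must lie in [0, 1), got {kappa}")
    if T < 2:
        raise ValueError("T must be at least 2")
    if kappa == 0.0:
        raw = np.full(T, 1.0 / T)
        return WeightScheme(0.0, raw, raw.copy())
    t = np.arange(1, T + 1)
    raw = kappa * (1.0 - kappa) ** (T - t)
    return WeightScheme(kappa, raw, raw / raw.sum())


def weighted_mean_curve(curves: np.ndarray, scheme: WeightScheme) -> np.ndarray:
    """Weighted average over years: ``mu(x_j) = sum_t w_t curve_t(x_j)``."""
    curves = np.asarray(curves, dtype=float)
    if curves.shape[0] != scheme.T:
        raise ValueError("row count does not match weight scheme length")
    return scheme.weights @ curves


def weight_rows_for_eigen(centered: np.ndarray, scheme: WeightScheme) -> np.ndarray:
    """Scale centered curves so their Gram matrix is the weighted covariance.

    Row ``t`` is multiplied by ``sqrt(w_t)``; the cross-product of the result
    equals ``sum_t w_t f*_t f*_t'``, the weighted sample covariance whose
    eigenfunctions the weighted FPCA uses.  (Scaling by ``w_t`` itself would
    square the weights inside the covariance.)
    """
    centered = np.asarray(centered, dtype=float)
    if centered.shape[0] != scheme.T:
        raise ValueError("row count does not match weight scheme length")
    return np.sqrt(scheme.weights)[:, None] * centered
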