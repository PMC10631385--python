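"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from wmfpca import (
    MortalitySurface,
    estimate_sigma,
    geometric_weights,
    smooth_surface,
    synthetic_data,
)

NO_PIVOT = 10_000  # pivot age beyond any grid: monotone constraint idle


def make_curvesets(surfaces, pivot_age=NO_PIVOT, smoothness="auto", kappa=0.0):
    """Smooth a list of surfaces and attach noise estimates."""
    out = []
    for s in surfaces:
        cs = smooth_surface(s, pivot_age=pivot_age, smoothness=smoothness)
        out.append(estimate_sigma(s, cs, geometric_weights(s.n_years, kappa)))
    return out


def raw_curvesets(surfaces):
    """Wrap surfaces as curve sets without smoothing (exact algebra tests)."""
    from wmfpca import SmoothCurveSet

    return [
        SmoothCurveSet(s.population_id, s.ages, s.years, s.log_rates.copy())
        for s in surfaces
    ]


def surface_from_matrix(log_rates, population_id="pop"):
    log_rates = np.asarray(log_rates, dtype=float)
    T, J = log_rates.shape
    return MortalitySurface(
        population_id, np.arange(J), np.arange(1, T + 1), log_rates,
        np.zeros((T, J), dtype=bool),
    )


def stacked_mfpca_oracle(curvesets, scheme, n_components=None):
    """Brute-force multivariate FPCA: eigendecompose the stacked (pJ x pJ)
    weighted covariance of the concatenated curves directly.

    Independent of the score-matrix algorithm; returns (eigenvalues,
    eigenfunctions (n, pJ), fitted demeaned stacked curves (T, pJ)).
    """
    T = curvesets[0].n_years
    dx = float(curvesets[0].ages[1] - curvesets[0].ages[0])
    stacked = np.hstack([cs.curves for cs in curvesets])
    mean = scheme.weights @ stacked
    centered = stacked - mean
    rows = np.sqrt(scheme.weights)[:, None] * centered
    K = rows.T @ rows * (T / (T - 1.0))
    lam, vecs = np.linalg.eigh(K * dx)
    lam, vecs = lam[::-1], vecs[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    n = len(lam) if n_components is None else n_components
    phi = vecs[:, :n].T / np.sqrt(dx)
    scores = centered @ phi.T * dx
    fitted = scores @ phi
    return lam, phi, fitted


def life_table_oracle(log_m):
    """Brute-force period life table, coded independently (explicit loops)."""
    m = [float(np.exp(v)) for v in log_m]
    A = len(m)
    q = []
    for mx in m:
        qx = mx / (1.0 + 0.5 * mx)
        q.append(min(qx, 1.0))
    l = [1.0]
    for x in range(A - 1):
        l.append(l[x] * (1.0 - q[x]))
    L = []
    for x in range(A):
        if x == A - 1:
            L.append(l[x] / m[x])
        else:
            L.append(l[x] - 0.5 * l[x] * q[x])
    e = []
    for x in range(A):
        if l[x] > 0:
            e.append(sum(L[x:]) / l[x])
        else:
            e.append(0.0)
    return np.array(e)


@pytest.fixture(scope="session")
def small_synthetic():
    """p=2, T=60, J=21 coherent dataset with ground truth."""
    spec = synthetic_data.default_spec(p=2, T=60, J=21, K=2, L=1, seed=11)
    surfaces, truth = synthetic_data.generate(spec)
    return surfaces, truth


@pytest.fixture(scope="session")
def small_curvesets(small_synthetic):
    surfaces, _ = small_synthetic
    return make_curvesets(surfaces)
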