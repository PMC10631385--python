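"""Synthetic multi-population log-mortality surfaces with known ground truth.

Surfaces are generated from the coherent decomposition

    Y_t^(i)(x) = mu(x) + eta^(i)(x) + G_t(x) + Z_t^(i)(x) + sigma(x) e_t^(i)(x)

where ``mu`` is the grand mean curve, ``eta^(i)`` are fixed population
deviations summing to zero across populations, the common trend
``G_t = sum_k beta_{t,k} phi_k`` has random-walk-with-drift scores (mortality
improves secularly, so the common component is non-stationary), and the
population deviation trend ``Z_t^(i) = sum_l gamma_{t,l} phi_l^(i)`` has
stationary AR(1) scores shared across populations with population-specific
multivariate-orthonormal eigenfunctions.  ``e`` is i.i.d. standard normal and
``sigma(x)`` lets observation noise vary with age.

Simulated common scores are demeaned over the sample so the generated ``G_t``
has exactly zero sample mean — the identifiability convention the estimators
assume.  The deviation eigenfunctions are built to sum to zero across
populations, so the population-average curve carries the common trend only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_hmd import MortalitySurface

__all__ = ["SyntheticSpec", "GroundTruth", "default_spec", "generate", "trend_break_surfaces"]

_ORTHO_TOL = 1e-10


@dataclass
class SyntheticSpec:
    """Parameters of the coherent synthetic generator.

    ``common_score_model`` holds one ``(drift, innovation_sd)`` pair per
    common component; ``deviation_score_model`` one ``(ar_coef,
    innovation_sd)`` pair per deviation component, with ``|ar_coef| < 1``.
    ``deviation_basis`` has shape ``(L, p, J)`` and is multivariate
    orthonormal: ``sum_i sum_j phi_l^(i)(x_j) phi_m^(i)(x_j) dx = delta_lm``.
    """

    p: int
    T: int
    ages: np.ndarray
    mu: np.ndarray
    eta: np.ndarray  # (p, J), rows sum to zero across populations
    common_basis: np.ndarray  # (K, J)
    common_score_model: list  # [(drift, innovation_sd)] * K
    deviation_basis: np.ndarray  # (L, p, J)
    deviation_score_model: list  # [(ar_coef, innovation_sd)] * L
    noise_sd: np.ndarray  # (J,)
    seed: int

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        for name in ("mu", "eta", "common_basis", "deviation_basis", "noise_sd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    @property
    def J(self) -> int:
        return len(self.ages)

    @property
    def K(self) -> int:
        return self.common_basis.shape[0]

    @property
    def L(self) -> int:
        return self.deviation_basis.shape[0]

    def validate(self) -> None:
        J = self.J
        dx = 1.0
        if self.mu.shape != (J,) or self.eta.shape != (self.p, J):
            raise ValueError("mu/eta shapes inconsistent with p and the age grid")
        if np.max(np.abs(self.eta.sum(axis=0))) > 1e-8:
            raise ValueError("eta curves must sum to the zero curve")
        gram = self.common_basis @ self.common_basis.T * dx
        if np.max(np.abs(gram - np.eye(self.K))) > _ORTHO_TOL:
            raise ValueError("common basis is not orthonormal")
        flat = self.deviation_basis.reshape(self.L, -1)
        gram = flat @ flat.T * dx
        if np.max(np.abs(gram - np.eye(self.L))) > _ORTHO_TOL:
            raise ValueError("deviation basis is not multivariate orthonormal")
        for coef, _ in self.deviation_score_model:
            if not abs(coef) < 1.0:
                raise ValueError("AR(1) coefficients must lie strictly in (-1, 1)")
        if len(self.common_score_model) != self.K:
            raise ValueError("one (drift, sd) pair per common component required")
        if len(self.deviation_score_model) != self.L:
            raise ValueError("one (ar, sd) pair per deviation component required")
        if self.noise_sd.shape != (J,) or np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be a non-negative J-vector")


@dataclass
class GroundTruth:
    """Latent quantities behind one generated dataset."""

    mu: np.ndarray
    eta: np.ndarray
    common_basis: np.ndarray
    deviation_basis: np.ndarray
    common_scores: np.ndarray  # (T, K), sample-demeaned
    deviation_scores: np.ndarray  # (T, L)
    G: np.ndarray  # (T, J)
    Z: np.ndarray  # (p, T, J)
    noiseless: np.ndarray  # (p, T, J) = mu + eta + G + Z
    spec: SyntheticSpec = field(repr=False, default=None)  # type: ignore[assignment]


def _smooth_seed_curves(x01: np.ndarray, count: int) -> np.ndarray:
    """Deterministic family of smooth curves used to seed Gram-Schmidt."""
    curves = [np.ones_like(x01), x01, x01**2]
    k = 1
    while len(curves) < count:
        curves.append(np.sin(np.pi * k * x01))
        curves.append(np.cos(np.pi * k * x01))
        k += 1
    return np.array(curves[:count])


def _gram_schmidt(curves: np.ndarray, dx: float = 1.0) -> np.ndarray:
    """Orthonormalize rows under the quadrature inner product ``sum v w dx``."""
    out = []
    for v in np.asarray(curves, dtype=float):
        v = v.copy()
        for u in out:
            v -= (v @ u) * dx * u
        norm = np.sqrt(v @ v * dx)
        if norm < 1e-10:
            raise ValueError("age grid too small to orthonormalize the basis")
        out.append(v / norm)
    return np.array(out)


def _zero_sum_directions(p: int, L: int) -> np.ndarray:
    """L unit vectors in R^p, each summing to zero (contrast directions)."""
    basis = []
    for m in range(1, p):
        v = np.zeros(p)
        v[:m] = 1.0 / m
        v[m] = -1.0
        basis.append(v / np.linalg.norm(v))
    basis = _gram_schmidt(np.array(basis))
    return np.array([basis[l % (p - 1)] for l in range(L)])


def default_spec(
    p: int,
    T: int,
    J: int,
    K: int,
    L: int,
    seed: int,
    noise_sd: float | np.ndarray = 0.05,
    ar_coef: float = 0.6,
    ar_sd: float = 0.2,
) -> SyntheticSpec:
    """Reproducible spec with smooth orthonormal bases.

    The mean curve has a Gompertz-like old-age slope with an infant-mortality
    bump; common-score drifts alternate a dominant mortality-improvement
    component (drift −0.20/year) with weaker secondary drifts so that more
    than one common component carries variance.  Deviation scores default to
    AR(1) with coefficient 0.6 and innovation s.d. 0.2, a mildly persistent
    stationary gap between populations.
    """
    if p < 2 or K < 1 or L < 1:
        raise ValueError("need p >= 2, K >= 1, L >= 1")
    if J < K + L + 1:
        raise ValueError("J must be at least K + L + 1 to orthonormalize the bases")
    rng = np.random.default_rng(seed)
    ages = np.arange(J)
    x01 = ages / max(J - 1, 1)

    # infant bump decays over ~an eighth of the age range so the curve stays
    # resolvable by smoothers with knots a few ages apart
    mu = -6.5 + 4.0 * x01**2 + 1.2 * np.exp(-8.0 * x01)

    joint = _gram_schmidt(_smooth_seed_curves(x01, K + L + 1))[1:]  # drop constant
    common_basis = joint[:K]
    dev_curves = joint[K : K + L]
    directions = _zero_sum_directions(p, L)
    deviation_basis = directions[:, :, None] * dev_curves[:, None, :] / np.sqrt(1.0)

    # smooth random eta curves, forced to sum to zero across populations
    eta = np.array(
        [
            0.25 * rng.standard_normal() * x01
            + 0.15 * rng.standard_normal() * np.sin(np.pi * x01)
            for _ in range(p)
        ]
    )
    eta -= eta.mean(axis=0, keepdims=True)

    drifts = [-0.20, 0.08, -0.05, 0.03]
    sds = [0.15, 0.10, 0.08, 0.06]
    common_score_model = [
        (drifts[k % len(drifts)] * (1 + k // len(drifts)), sds[k % len(sds)])
        for k in range(K)
    ]
    deviation_score_model = [(ar_coef, ar_sd)] * L
    noise = np.full(J, float(noise_sd)) if np.ndim(noise_sd) == 0 else np.asarray(noise_sd, float)

    return SyntheticSpec(
        p=p,
        T=T,
        ages=ages,
        mu=mu,
        eta=eta,
        common_basis=common_basis,
        common_score_model=common_score_model,
        deviation_basis=deviation_basis,
        deviation_score_model=deviation_score_model,
        noise_sd=noise,
        seed=seed,
    )


def generate(spec: SyntheticSpec, n_years: int | None = None):
    """Simulate surfaces from ``spec``.

    Returns ``(surfaces, truth)`` where ``surfaces`` is a list of ``p``
    :class:`~wmfpca.io_hmd.MortalitySurface` and ``truth`` records every
    latent curve and score.  Deterministic given ``spec.seed``.  ``n_years``
    overrides ``spec.T`` (e.g. to generate holdout years for evaluation).
    """
    spec.validate()
    T = int(n_years) if n_years is not None else spec.T
    rng = np.random.default_rng(spec.seed)
    K, L, p, J = spec.K, spec.L, spec.p, spec.J

    beta = np.empty((T, K))
    for k, (drift, sd) in enumerate(spec.common_score_model):
        steps = drift + sd * rng.standard_normal(T)
        beta[:, k] = np.cumsum(steps)
    beta -= beta.mean(axis=0, keepdims=True)  # G_t has zero sample mean

    gamma = np.empty((T, L))
    for l, (coef, sd) in enumerate(spec.deviation_score_model):
        x = np.empty(T)
        stat_sd = sd / np.sqrt(1.0 - coef**2) if sd > 0 else 0.0
        x[0] = stat_sd * rng.standard_normal()
        innov = sd * rng.standard_normal(T - 1)
        for t in range(1, T):
            x[t] = coef * x[t - 1] + innov[t - 1]
        gamma[:, l] = x

    G = beta @ spec.common_basis  # (T, J)
    Z = np.einsum("tl,lpj->ptj", gamma, spec.deviation_basis)  # (p, T, J)
    noiseless = spec.mu[None, None, :] + spec.eta[:, None, :] + G[None, :, :] + Z

    years = np.arange(1, T + 1)
    surfaces = []
    for i in range(p):
        noise = spec.noise_sd[None, :] * rng.standard_normal((T, J))
        log_rates = noiseless[i] + noise
        surfaces.append(
            MortalitySurface(
                population_id=f"pop{i + 1}",
                ages=spec.ages,
                years=years,
                log_rates=log_rates,
                missing_mask=np.zeros((T, J), dtype=bool),
            )
        )
    truth = GroundTruth(
        mu=spec.mu,
        eta=spec.eta,
        common_basis=spec.common_basis,
        deviation_basis=spec.deviation_basis,
        common_scores=beta,
        deviation_scores=gamma,
        G=G,
        Z=Z,
        noiseless=noiseless,
        spec=spec,
    )
    return surfaces, truth


def trend_break_surfaces(
    p: int,
    T: int,
    J: int,
    seed: int,
    break_frac: float = 2.0 / 3.0,
    pre_drift: float = -0.25,
    post_drift: float = 0.0,
    steady_drift: float = -0.15,
    score_sd: float = 0.03,
    noise_sd: float = 0.02,
):
    """Surfaces where the *direction* of mortality improvement changes.

    Two orthonormal age profiles evolve over time: the first drifts at
    ``pre_drift`` per year until the break (at ``break_frac * T``) and at
    ``post_drift`` afterwards; the second drifts at ``steady_drift``
    throughout.  With the default values the historically dominant profile
    stalls after the break, so on recent data nearly all variation lies along
    the second profile.  Geometric weights with ``kappa > 0`` concentrate the
    estimated eigenfunctions and the mean on the recent regime and should
    forecast better than uniform weights.  Setting ``pre_drift ==
    post_drift`` gives a no-break control.  Returns ``(surfaces, noiseless)``
    with ``noiseless`` of shape ``(p, T, J)``.
    """
    rng = np.random.default_rng(seed)
    ages = np.arange(J)
    x01 = ages / max(J - 1, 1)
    mu = -6.5 + 4.0 * x01**2 + 1.2 * np.exp(-20.0 * x01)
    shapes = _gram_schmidt(np.array([np.ones(J), x01]))  # flat and tilted profiles
    eta = np.array([(i - (p - 1) / 2.0) * 0.3 * np.ones(J) for i in range(p)])
    eta -= eta.mean(axis=0, keepdims=True)

    t_break = int(np.floor(break_frac * T))
    drift1 = np.where(np.arange(T) < t_break, pre_drift, post_drift)
    s1 = np.cumsum(drift1 + score_sd * rng.standard_normal(T))
    s2 = np.cumsum(steady_drift + score_sd * rng.standard_normal(T))
    s1 -= s1.mean()
    s2 -= s2.mean()
    G = np.outer(s1, shapes[0]) + np.outer(s2, shapes[1])

    noiseless = mu[None, None, :] + eta[:, None, :] + G[None, :, :]
    years = np.arange(1, T + 1)
    surfaces = []
    for i in range(p):
        log_rates = noiseless[i] + noise_sd * rng.standard_normal((T, J))
        surfaces.append(
            MortalitySurface(
                population_id=f"pop{i + 1}",
                ages=ages,
                years=years,
                log_rates=log_rates,
                missing_mask=np.zeros((T, J), dtype=bool),
            )
        )
    return surfaces, noiseless
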