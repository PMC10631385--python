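"""Functional principal component analysis on a dense regular age grid.

Univariate FPCA discretizes the covariance operator: with curves observed on
a regular grid ``x_1..x_J`` (spacing ``dx``), the eigenproblem
``(Gamma phi)(x) = lambda phi(x)`` becomes the symmetric matrix eigenproblem
``(K dx) v = lambda v`` where ``K`` is the (weighted) sample covariance of the
centered curves and ``phi = v / sqrt(dx)`` so that eigenfunctions are
orthonormal under the quadrature inner product ``<f, g> = sum_j f g dx``.

Multivariate FPCA over ``p`` populations follows the score-matrix algorithm:
run a univariate FPCA per population, stack the score blocks into
``Xi (T x pN)``, eigendecompose the joint score covariance ``Zhat``, and map
its eigenvectors back to per-population multivariate eigenfunctions
``psi_n^(i) = sum_m [c_n]_m^(i) phi_m^(i)`` with shared scores
``rho_{t,n} = Xi c_n``.

Conventions used throughout:

* scores are projections of the *unweighted* centered curves onto the
  (weighted) eigenfunctions, so score series carry no artificial decay and
  can be extrapolated as time series;
* ``Zhat`` is the weighted score covariance scaled by ``T / (T - 1)`` (with
  uniform weights this is exactly ``Xi' Xi / (T - 1)``); the scalar affects
  only the eigenvalue scale, never eigenvectors, scores or forecasts;
* each eigenfunction's sign is fixed so its quadrature integral is positive
  (largest-magnitude value positive when the integral vanishes), making
  output deterministic across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import SmoothCurveSet
from .weighting import WeightScheme, weighted_mean_curve, weight_rows_for_eigen

__all__ = [
    "UnivariateFPCA",
    "MultivariateFPCA",
    "ufpca",
    "ufpca_matrix",
    "select_ncomp",
    "mfpca_from_ufpca",
    "reconstruct",
]


def select_ncomp(eigenvalues: np.ndarray, P: float = 0.9) -> int:
    """Smallest N whose leading eigenvalues explain a fraction >= P."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("empty spectrum")
    if np.any(lam < -1e-10 * max(lam.max(initial=0.0), 1.0)):
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(lam) > 1e-10 * max(lam.max(initial=0.0), 1.0)):
        raise ValueError("eigenvalues must be non-increasing")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero eigenvalue spectrum")
    frac = np.cumsum(lam) / total
    return int(np.searchsorted(frac, P - 1e-12) + 1)


def _fix_signs(eigenfunctions: np.ndarray, dx: float) -> np.ndarray:
    """Flip each row so its integral (or peak value) is positive."""
    out = eigenfunctions.copy()
    for n in range(out.shape[0]):
        integral = out[n].sum() * dx
        if abs(integral) > 1e-12:
            if integral < 0:
                out[n] = -out[n]
        elif out[n][np.argmax(np.abs(out[n]))] < 0:
            out[n] = -out[n]
    return out


@dataclass
class UnivariateFPCA:
    """Weighted univariate FPCA fit for one population."""

    population_id: str
    ages: np.ndarray
    dx: float
    mean: np.ndarray  # (J,)
    eigenfunctions: np.ndarray  # (N, J)
    eigenvalues: np.ndarray  # (N,) retained
    all_eigenvalues: np.ndarray  # full spectrum
    scores: np.ndarray  # (T, N)
    explained: np.ndarray  # (N,)
    P: float
    weights: np.ndarray  # (T,) normalized observation weights

    @property
    def N(self) -> int:
        return len(self.eigenvalues)

    @property
    def T(self) -> int:
        return self.scores.shape[0]


def ufpca_matrix(
    curves: np.ndarray,
    ages: np.ndarray,
    scheme: WeightScheme,
    P: float = 0.9,
    n_components: int | str | None = None,
    population_id: str = "",
    max_components: int | None = None,
) -> UnivariateFPCA:
    """Univariate FPCA of a ``(T, J)`` curve matrix.

    ``n_components`` overrides the cumulative-variance rule (``"all"`` keeps
    the full spectrum, useful for exact reconstructions and oracle checks).
    """
    curves = np.asarray(curves, dtype=float)
    T, J = curves.shape
    if T < 3:
        raise ValueError("need at least 3 curves")
    ages = np.asarray(ages)
    dx = float(ages[1] - ages[0]) if J > 1 else 1.0

    mean = weighted_mean_curve(curves, scheme)
    centered = curves - mean
    rows = weight_rows_for_eigen(centered, scheme)
    K = rows.T @ rows  # weighted covariance sum_t w_t f* f*'
    if not np.all(np.isfinite(K)):
        raise ValueError("covariance matrix is not finite")
    lam, vecs = np.linalg.eigh(K * dx)
    order = np.argsort(lam)[::-1]
    lam, vecs = np.clip(lam[order], 0.0, None), vecs[:, order]

    if n_components == "all":
        N = J
    elif n_components is not None:
        N = int(n_components)
    else:
        try:
            N = select_ncomp(lam, P)
        except ValueError:
            N = 1  # zero-variance input (e.g. identical curves)
    if max_components is not None:
        N = min(N, max_components)

    phi = _fix_signs(vecs[:, :N].T / np.sqrt(dx), dx)
    scores = centered @ phi.T * dx
    explained = lam[:N] / lam.sum() if lam.sum() > 0 else np.zeros(N)
    return UnivariateFPCA(
        population_id=population_id,
        ages=ages,
        dx=dx,
        mean=mean,
        eigenfunctions=phi,
        eigenvalues=lam[:N],
        all_eigenvalues=lam,
        scores=scores,
        explained=explained,
        P=P,
        weights=scheme.weights.copy(),
    )


def ufpca(
    curveset: SmoothCurveSet,
    scheme: WeightScheme,
    P: float = 0.9,
    n_components: int | str | None = None,
    max_components: int | None = None,
) -> UnivariateFPCA:
    """Weighted univariate FPCA of a smoothed curve set."""
    return ufpca_matrix(
        curveset.curves,
        curveset.ages,
        scheme,
        P=P,
        n_components=n_components,
        population_id=curveset.population_id,
        max_components=max_components,
    )


@dataclass
class MultivariateFPCA:
    """Joint FPCA of several populations built from univariate score blocks."""

    uni_fits: list = field(repr=False)
    Xi: np.ndarray  # (T, pN_total)
    Zhat: np.ndarray  # joint score covariance
    eigvecs: np.ndarray  # full (pN_total, pN_total), columns c_n
    eigvals: np.ndarray  # full spectrum nu_n
    N: int  # retained multivariate components
    mv_eigenfunctions: np.ndarray  # (p, N, J)
    mv_scores: np.ndarray  # (T, N)
    explained: np.ndarray
    block_slices: list  # per-population column slices of Xi

    @property
    def p(self) -> int:
        return len(self.uni_fits)

    @property
    def T(self) -> int:
        return self.Xi.shape[0]

    @property
    def dx(self) -> float:
        return self.uni_fits[0].dx

    def population_index(self, population_id: str) -> int:
        for i, fit in enumerate(self.uni_fits):
            if fit.population_id == population_id:
                return i
        raise KeyError(population_id)


def mfpca_from_ufpca(
    fits: list,
    P: float = 0.9,
    n_components: int | str | None = None,
) -> MultivariateFPCA:
    """Combine univariate fits into a multivariate FPCA.

    With ``p = 1`` this degenerates to the univariate fit itself (the joint
    score covariance is already diagonal), which is the independent-FPCA
    baseline.
    """
    T = fits[0].T
    if any(f.T != T for f in fits):
        raise ValueError("all univariate fits must share the same year count")
    w = fits[0].weights
    if any(not np.allclose(f.weights, w) for f in fits):
        raise ValueError("all univariate fits must share the weight scheme")

    blocks, slices, start = [], [], 0
    for f in fits:
        blocks.append(f.scores)
        slices.append(slice(start, start + f.N))
        start += f.N
    Xi = np.hstack(blocks)
    Zhat = Xi.T @ (w[:, None] * Xi) * (T / (T - 1.0))

    nu, C = np.linalg.eigh(Zhat)
    order = np.argsort(nu)[::-1]
    nu, C = np.clip(nu[order], 0.0, None), C[:, order]

    if n_components == "all":
        N = Xi.shape[1]
    elif n_components is not None:
        N = int(n_components)
    else:
        try:
            N = select_ncomp(nu, P)
        except ValueError:
            N = 1  # zero-variance score blocks

    p, J, dx = len(fits), len(fits[0].mean), fits[0].dx
    psi = np.empty((p, N, J))
    for n in range(N):
        for i, f in enumerate(fits):
            psi[i, n] = C[slices[i], n] @ f.eigenfunctions
    # one sign per multivariate component, judged on the concatenated function
    flat = _fix_signs(psi.transpose(1, 0, 2).reshape(N, p * J), dx)
    signs = np.sign(np.einsum("npj,npj->n", flat.reshape(N, p, J), psi.transpose(1, 0, 2)))
    signs[signs == 0] = 1.0  # null components: leave untouched
    psi = flat.reshape(N, p, J).transpose(1, 0, 2)
    C = C.copy()
    C[:, :N] *= signs[None, :]

    rho = Xi @ C[:, :N]
    explained = nu[:N] / nu.sum() if nu.sum() > 0 else np.zeros(N)
    return MultivariateFPCA(
        uni_fits=list(fits),
        Xi=Xi,
        Zhat=Zhat,
        eigvecs=C,
        eigvals=nu,
        N=N,
        mv_eigenfunctions=psi,
        mv_scores=rho,
        explained=explained,
        block_slices=slices,
    )


def reconstruct(mfpca: MultivariateFPCA, n_components: int, population_i: int) -> np.ndarray:
    """Truncated Karhunen-Loeve fit of the demeaned curves of one population:
    ``sum_{n<=n_components} rho_{t,n} psi_n^(i)(x_j)``."""
    if not 0 <= n_components <= mfpca.N:
        raise ValueError(f"n_components must be in [0, {mfpca.N}]")
    if n_components == 0:
        return np.zeros((mfpca.T, mfpca.mv_eigenfunctions.shape[2]))
    return mfpca.mv_scores[:, :n_components] @ mfpca.mv_eigenfunctions[population_i, :n_components]
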