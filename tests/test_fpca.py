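"""Univariate and multivariate FPCA: component selection, orthonormality,
score properties, reconstruction, and brute-force oracle equivalence."""

import numpy as np
import pytest

from conftest import raw_curvesets, stacked_mfpca_oracle, surface_from_matrix
from wmfpca import (
    SmoothCurveSet,
    geometric_weights,
    mfpca_from_ufpca,
    reconstruct,
    select_ncomp,
    synthetic_data,
    ufpca,
    ufpca_matrix,
)


def curveset(matrix, pid="pop"):
    T, J = np.asarray(matrix).shape
    return SmoothCurveSet(pid, np.arange(J), np.arange(1, T + 1), np.asarray(matrix, float))


class TestSelectNcomp:
    @pytest.mark.parametrize(
        "spectrum, P, expected",
        [((0.8, 0.15, 0.05), 0.9, 2), ((0.9, 0.06, 0.04), 0.9, 1), ((1.0,), 0.5, 1),
         ((1.0,), 1.0, 1), ((0.5, 0.3, 0.2), 0.999, 3)],
    )
    def test_examples(self, spectrum, P, expected):
        assert select_ncomp(np.array(spectrum), P) == expected

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            select_ncomp(np.zeros(3), 0.9)

    def test_increasing_spectrum_rejected(self):
        with pytest.raises(ValueError):
            select_ncomp(np.array([0.1, 0.9]), 0.9)


class TestUnivariate:
    def test_rank_one_identity(self):
        rng = np.random.default_rng(0)
        J, T = 13, 30
        v = rng.standard_normal(J)
        v /= np.linalg.norm(v)  # unit norm, dx = 1
        a = rng.standard_normal(T) * 2.0
        fit = ufpca(curveset(np.outer(a, v)), geometric_weights(T, 0.0))
        assert fit.N == 1
        assert fit.all_eigenvalues[1:].max() < 1e-12 * fit.all_eigenvalues[0]
        phi = fit.eigenfunctions[0]
        sign = np.sign(phi @ v)
        assert np.allclose(phi, sign * v, atol=1e-10)
        centered_a = a - a.mean()
        assert np.allclose(fit.scores[:, 0], sign * centered_a, atol=1e-10)

    def test_recovers_known_basis_noiseless(self):
        # eigenfunctions are identified when scores are exactly uncorrelated
        # in-sample with distinct variances; construct such data directly
        spec = synthetic_data.default_spec(p=2, T=120, J=21, K=2, L=1, seed=1)
        rng = np.random.default_rng(1)
        a = rng.standard_normal(120) * 3.0
        a -= a.mean()
        b = rng.standard_normal(120)
        b -= b.mean()
        b -= (b @ a) / (a @ a) * a  # exactly uncorrelated scores
        curves = spec.mu + np.outer(a, spec.common_basis[0]) \
            + np.outer(b, spec.common_basis[1])
        fit = ufpca(curveset(curves), geometric_weights(120, 0.0), n_components=2)
        for k in range(2):
            inner = np.abs(fit.eigenfunctions @ spec.common_basis[k]).max()
            assert inner >= 0.999

    def test_orthonormality_and_uncorrelated_scores(self, small_curvesets):
        for kappa in (0.0, 0.25):
            scheme = geometric_weights(60, kappa)
            fit = ufpca(small_curvesets[0], scheme, n_components=4)
            gram = fit.eigenfunctions @ fit.eigenfunctions.T * fit.dx
            assert np.max(np.abs(gram - np.eye(4))) < 1e-8
            # weighted correlation of score columns vanishes
            s = fit.scores
            cov = s.T @ (scheme.weights[:, None] * s)
            off = cov - np.diag(np.diag(cov))
            denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
            assert np.max(np.abs(off / denom)) < 1e-8

    def test_sign_convention_deterministic(self, small_curvesets):
        scheme = geometric_weights(60, 0.1)
        f1 = ufpca(small_curvesets[0], scheme)
        f2 = ufpca(small_curvesets[0], scheme)
        assert np.array_equal(f1.eigenfunctions, f2.eigenfunctions)
        assert all(phi.sum() > -1e-12 for phi in f1.eigenfunctions)


class TestMultivariate:
    def test_identical_populations_hand_eigendecomposition(self):
        # two identical rank-1 populations: joint score covariance is
        # [[lam, lam], [lam, lam]] so c1 = (1,1)/sqrt(2), psi = phi/sqrt(2),
        # rho = sqrt(2) beta
        rng = np.random.default_rng(2)
        J, T = 11, 24
        v = rng.standard_normal(J)
        v /= np.linalg.norm(v)
        a = rng.standard_normal(T)
        cs = curveset(np.outer(a, v))
        scheme = geometric_weights(T, 0.0)
        fits = [ufpca(cs, scheme, n_components=1),
                ufpca(curveset(np.outer(a, v), "pop2"), scheme, n_components=1)]
        mf = mfpca_from_ufpca(fits, n_components=1)
        c1 = mf.eigvecs[:, 0]
        assert np.allclose(np.abs(c1), 1 / np.sqrt(2), atol=1e-10)
        assert mf.eigvals[1] < 1e-10 * mf.eigvals[0]
        for i in range(2):
            assert np.allclose(
                mf.mv_eigenfunctions[i, 0],
                fits[0].eigenfunctions[0] / np.sqrt(2) * np.sign(c1[0]),
                atol=1e-10,
            )
        assert np.allclose(
            mf.mv_scores[:, 0], np.sqrt(2) * fits[0].scores[:, 0] * np.sign(c1[0]),
            atol=1e-10,
        )

    def test_uncorrelated_blocks_diagonal_covariance(self):
        # score blocks with variances 2 and 1 and zero cross-correlation:
        # nu proportional to (2, 1) and c_n = standard basis vectors
        J, T = 9, 8
        v1 = np.zeros(J); v1[0] = 1.0
        v2 = np.zeros(J); v2[1] = 1.0
        a = np.array([1, 1, -1, -1, 1, 1, -1, -1]) * np.sqrt(2.0)
        b = np.array([1, -1, 1, -1, 1, -1, 1, -1]) * 1.0
        scheme = geometric_weights(T, 0.0)
        fits = [ufpca(curveset(np.outer(a, v1), "A"), scheme, n_components=1),
                ufpca(curveset(np.outer(b, v2), "B"), scheme, n_components=1)]
        mf = mfpca_from_ufpca(fits, n_components=2)
        assert np.isclose(mf.eigvals[0] / mf.eigvals[1], 2.0)
        assert np.allclose(np.abs(mf.eigvecs[:, :2]), np.eye(2), atol=1e-10)

    def test_multivariate_orthonormality_and_uncorrelated_scores(self, small_curvesets):
        for kappa in (0.0, 0.2):
            scheme = geometric_weights(60, kappa)
            fits = [ufpca(cs, scheme, n_components=3) for cs in small_curvesets]
            mf = mfpca_from_ufpca(fits, n_components=4)
            psi = mf.mv_eigenfunctions  # (p, N, J)
            gram = np.einsum("inj,imj->nm", psi, psi) * mf.dx
            assert np.max(np.abs(gram - np.eye(mf.N))) < 1e-8
            r = mf.mv_scores
            cov = r.T @ (scheme.weights[:, None] * r)
            denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
            off = (cov - np.diag(np.diag(cov))) / denom
            assert np.max(np.abs(off)) < 1e-8

    def test_total_variance_conservation(self, small_curvesets):
        scheme = geometric_weights(60, 0.15)
        fits = [ufpca(cs, scheme, n_components="all") for cs in small_curvesets]
        mf = mfpca_from_ufpca(fits, n_components="all")
        assert np.isclose(mf.eigvals.sum(), np.trace(mf.Zhat), rtol=1e-10)
        block_var = sum(
            float(np.sum(f.scores.T @ (scheme.weights[:, None] * f.scores)
                         * (60 / 59.0) * np.eye(f.N)))
            for f in fits
        )
        assert np.isclose(mf.eigvals.sum(), block_var, rtol=1e-8)

    def test_p1_degenerates_to_univariate(self, small_curvesets):
        scheme = geometric_weights(60, 0.0)
        fit = ufpca(small_curvesets[0], scheme, n_components=3)
        mf = mfpca_from_ufpca([fit], n_components=3)
        for n in range(3):
            assert np.allclose(mf.mv_eigenfunctions[0, n], fit.eigenfunctions[n],
                               atol=1e-8)
            assert np.allclose(mf.mv_scores[:, n], fit.scores[:, n], atol=1e-8)

    def test_mismatched_T_rejected(self, small_curvesets):
        scheme = geometric_weights(60, 0.0)
        f1 = ufpca(small_curvesets[0], scheme)
        short = small_curvesets[1].subset_years(50)
        f2 = ufpca(short, geometric_weights(50, 0.0))
        with pytest.raises(ValueError):
            mfpca_from_ufpca([f1, f2])


class TestReconstruction:
    def test_full_rank_exact_and_monotone_error(self, small_curvesets):
        scheme = geometric_weights(60, 0.1)
        fits = [ufpca(cs, scheme, n_components="all") for cs in small_curvesets]
        mf = mfpca_from_ufpca(fits, n_components="all")
        # nested projections give monotone error in the weighted integrated
        # squared norm the components optimize (max-abs error need not be
        # monotone); the full-rank identity is checked in max-abs
        wsq = []
        for n in range(mf.N + 1):
            err = 0.0
            for i, cs in enumerate(small_curvesets):
                resid = reconstruct(mf, n, i) + fits[i].mean - cs.curves
                err += float(scheme.weights @ np.sum(resid * resid, axis=1)) * mf.dx
            wsq.append(err)
        full_maxabs = max(
            np.max(np.abs(reconstruct(mf, mf.N, i) + fits[i].mean - cs.curves))
            for i, cs in enumerate(small_curvesets)
        )
        assert full_maxabs <= 1e-8
        assert np.all(np.diff(wsq) <= 1e-12 * max(wsq[0], 1.0))

    def test_zero_components_zero_matrix(self, small_curvesets):
        scheme = geometric_weights(60, 0.0)
        fits = [ufpca(cs, scheme) for cs in small_curvesets]
        mf = mfpca_from_ufpca(fits)
        assert np.all(reconstruct(mf, 0, 0) == 0.0)

    def test_out_of_range_rejected(self, small_curvesets):
        scheme = geometric_weights(60, 0.0)
        mf = mfpca_from_ufpca([ufpca(cs, scheme) for cs in small_curvesets])
        with pytest.raises(ValueError):
            reconstruct(mf, mf.N + 1, 0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("kappa", [0.0, 0.2])
    def test_matches_stacked_covariance_eigendecomposition(self, kappa):
        spec = synthetic_data.default_spec(p=2, T=40, J=15, K=2, L=1, seed=13)
        surfaces, _ = synthetic_data.generate(spec)
        csets = raw_curvesets(surfaces)
        scheme = geometric_weights(40, kappa)
        fits = [ufpca(cs, scheme, n_components="all") for cs in csets]
        mf = mfpca_from_ufpca(fits, n_components="all")
        lam, _, fitted = stacked_mfpca_oracle(csets, scheme)
        assert np.max(np.abs(mf.eigvals - lam)) <= 1e-6 * lam.max()
        mine = np.hstack([reconstruct(mf, mf.N, i) for i in range(2)])
        assert np.max(np.abs(mine - fitted)) <= 1e-6
        # truncated fits agree too
        _, _, fitted3 = stacked_mfpca_oracle(csets, scheme, n_components=3)
        mf3 = mfpca_from_ufpca(fits, n_components=3)
        mine3 = np.hstack([reconstruct(mf3, 3, i) for i in range(2)])
        assert np.max(np.abs(mine3 - fitted3)) <= 1e-6
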