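"""MLEM, PWLS+CG and the robust least-squares core."""

import numpy as np
import pytest
import scipy.sparse as sp

import robustpet as rp
from robustpet.penalty import PenaltyModel, grid_laplacian
from robustpet.robust import lambda_lower_bound


def identity_system(n):
    geom = rp.ScanGeometry(grid_nx=n, grid_ny=1, n_angles=1, n_bins=n)
    return geom, rp.SystemMatrix(geom, sp.identity(n, format="csr"))


class TestPenalty:
    def test_symmetric_psd_and_constant_null(self, small_geom, rng):
        pen = PenaltyModel(small_geom)
        Q = pen.Q
        assert (Q != Q.T).nnz == 0
        for _ in range(5):
            v = rng.standard_normal(Q.shape[0])
            assert v @ (Q @ v) >= -1e-10
        const = np.ones(Q.shape[0])
        assert const @ (Q @ const) == pytest.approx(0.0, abs=1e-9)

    def test_laplacian_is_neighbour_roughness(self):
        geom = rp.ScanGeometry(grid_nx=3, grid_ny=2, n_angles=1, n_bins=1)
        Q = grid_laplacian(geom)
        x = np.array([0.0, 1.0, 3.0, 2.0, 2.0, 2.0])
        img = x.reshape(2, 3)
        expected = (np.sum(np.diff(img, axis=0) ** 2)
                    + np.sum(np.diff(img, axis=1) ** 2))
        assert x @ (Q @ x) == pytest.approx(expected)

    def test_ridged_is_invertible(self, tiny_geom):
        pen = PenaltyModel(tiny_geom)
        Qr = pen.ridged().toarray()
        assert np.linalg.cond(Qr) < 1e14
        np.linalg.cholesky(Qr)


class TestMLEM:
    def test_identity_system_fixed_point(self):
        geom, D = identity_system(4)
        y = rp.Sinogram(geom, np.array([2.0, 5.0, 1.0, 7.0]), kind="corrected")
        res = rp.mlem_reconstruct(y, D, n_iter=1)
        np.testing.assert_allclose(res.image.values, y.values, rtol=1e-12)

    def test_loglik_nondecreasing_and_error_decreasing(self):
        geom = rp.ScanGeometry(grid_nx=16, grid_ny=16, n_angles=16, n_bins=23)
        D = rp.build_system_matrix(geom)
        truth = rp.shepp_logan_phantom(geom)
        y = rp.Sinogram(geom, D.entries @ truth.values, kind="corrected")
        res = rp.mlem_reconstruct(y, D, n_iter=50, x_true=truth)
        ll = np.array(res.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-7 * np.abs(ll[:-1]))
        err = np.array(res.error_trace)
        assert np.all(np.diff(err) <= 1e-12)

    def test_count_preservation(self, tiny_geom, tiny_D, tiny_phantom):
        """Detected counts are conserved over the rays that intersect the
        field of view (bins outside it hold pure contamination and carry no
        information about the image)."""
        proto = rp.ScanProtocol(total_counts=1000)
        p, d = rp.simulate_scan(tiny_phantom, tiny_D, proto, 0)
        y = rp.Sinogram(tiny_geom, np.maximum(
            rp.correct_sinogram(p, d, proto).values, 0), kind="corrected")
        sens = tiny_D.entries.T @ np.ones(tiny_geom.n_rays)
        assert np.all(sens > 0)
        in_fov = np.asarray(tiny_D.entries.sum(axis=1)).ravel() > 0
        detected = y.values[in_fov].sum()
        for n_iter in (1, 2, 3):
            res = rp.mlem_reconstruct(y, tiny_D, n_iter=n_iter)
            assert (tiny_D.entries @ res.image.values).sum() == pytest.approx(
                detected, rel=1e-10)

    def test_zero_sensitivity_voxels_frozen(self):
        geom = rp.ScanGeometry(grid_nx=2, grid_ny=1, n_angles=1, n_bins=1)
        # single central ray at angle 0 hits only one of the two pixels
        D = rp.build_system_matrix(geom)
        sens = np.asarray(D.entries.sum(axis=0)).ravel()
        assert np.count_nonzero(sens == 0) >= 1
        y = rp.Sinogram(geom, np.array([4.0]), kind="corrected")
        res = rp.mlem_reconstruct(y, D, n_iter=5)
        assert np.all(res.image.values[sens == 0] == 1.0)  # stays at x0


class TestPWLS:
    def test_square_invertible_unpenalized(self, rng):
        geom = rp.ScanGeometry(grid_nx=2, grid_ny=2, n_angles=2, n_bins=2)
        A = rng.random((4, 4)) + 4 * np.eye(4)
        D = rp.SystemMatrix(geom, sp.csr_matrix(A))
        y = rp.Sinogram(geom, rng.random(4), kind="corrected")
        pen = PenaltyModel(geom, beta=0.0)
        res = rp.pwls_cg_reconstruct(y, D, 1.0, pen, n_iter=200, tol=1e-30)
        direct = np.linalg.solve(A, y.values)
        np.testing.assert_allclose(res.image.values, np.maximum(direct, 0), atol=1e-8)

    def test_zero_operator_gives_zero(self, tiny_geom):
        D = rp.SystemMatrix(tiny_geom, sp.csr_matrix((tiny_geom.n_rays,
                                                      tiny_geom.n_voxels)))
        y = rp.Sinogram(tiny_geom, np.ones(tiny_geom.n_rays), kind="corrected")
        pen = PenaltyModel(tiny_geom, beta=2.0)
        res = rp.pwls_cg_reconstruct(y, D, 1.0, pen, n_iter=10)
        np.testing.assert_allclose(res.image.values, 0.0, atol=1e-12)

    def test_gradient_norm_reduced(self):
        geom = rp.ScanGeometry(grid_nx=16, grid_ny=16, n_angles=16, n_bins=23)
        D = rp.build_system_matrix(geom)
        truth = rp.shepp_logan_phantom(geom)
        rng = np.random.default_rng(1)
        y = rp.Sinogram(geom, D.entries @ truth.values + rng.normal(0, 0.5,
                        geom.n_rays), kind="corrected")
        pen = PenaltyModel(geom, beta=0.05)
        res = rp.pwls_cg_reconstruct(y, D, 1.0, pen, n_iter=300, tol=1e-26)
        b = D.entries.T @ y.values
        g0 = np.linalg.norm(b)  # gradient/residual at x0 = 0 (up to factor 2)
        assert res.grad_norm <= 1e-6 * g0

    def test_objective_nonincreasing(self, tiny_geom, tiny_D, tiny_phantom):
        y = rp.Sinogram(tiny_geom, tiny_D.entries @ tiny_phantom.values,
                        kind="corrected")
        pen = PenaltyModel(tiny_geom, beta=0.1)
        res = rp.pwls_cg_reconstruct(y, tiny_D, 1.0, pen, n_iter=40)
        obj = np.array(res.objective)
        assert np.all(np.diff(obj) <= 1e-9 * np.abs(obj[:-1]) + 1e-12)

    def test_non_positive_weight_rejected(self, tiny_geom, tiny_D):
        y = rp.Sinogram(tiny_geom, np.zeros(tiny_geom.n_rays), kind="corrected")
        with pytest.raises(ValueError):
            rp.pwls_cg_reconstruct(y, tiny_D, 0.0, PenaltyModel(tiny_geom), 5)


class TestRobustCore:
    def test_null_model_equals_regularized_wls(self, rng):
        A = rng.standard_normal((6, 4))
        b = rng.standard_normal(6)
        W = rng.uniform(0.5, 2.0, 6)
        Q = 0.3 * np.eye(4)
        U0 = rp.UncertaintyModel(None, None, None, phi=0.0)
        sol = rp.robust_ls_solve(A, b, W, Q, U0)
        direct = np.linalg.solve(Q + A.T @ (W[:, None] * A), A.T @ (W * b))
        np.testing.assert_allclose(sol.x, direct, atol=1e-10)
        assert sol.lam == 0.0

    def test_lambda_lower_rank_one(self):
        Mf = np.zeros((3, 1))
        Mf[0, 0] = 1.0
        U = rp.UncertaintyModel(Mf, np.eye(2), np.zeros(2), 1.0)
        assert lambda_lower_bound(np.ones(3), U) == pytest.approx(1.0)

    def test_lambda_lower_scaled_identity_fast_path(self, rng):
        W = rng.uniform(0.5, 2.0, 5)
        U = rp.UncertaintyModel(sp.identity(5).tocsr() * 0.7, sp.identity(3).tocsr(),
                                np.zeros(3), 1.0)
        dense = rp.UncertaintyModel(0.7 * np.eye(5), np.eye(3), np.zeros(3), 1.0)
        assert lambda_lower_bound(W, U) == pytest.approx(0.49 * W.max())
        assert lambda_lower_bound(W, dense) == pytest.approx(0.49 * W.max())

    def test_below_lower_bound_rejected(self, rng):
        A = rng.standard_normal((4, 2))
        U = rp.UncertaintyModel(np.eye(4), np.eye(2), np.zeros(2), 1.0)
        with pytest.raises(ValueError):
            rp.robust_ls_solve(A, rng.standard_normal(4), np.ones(4),
                               np.eye(2), U, lam=0.5)

    def test_worst_case_never_exceeds_nominal_solution(self, rng):
        """Grid min-max oracle: the robust solution's worst-case objective is
        no larger than the nominal solution's, over sampled contractions."""
        for trial in range(3):
            r = np.random.default_rng(100 + trial)
            m, n = 3, 2
            A = r.standard_normal((m, n))
            b = r.standard_normal(m)
            W = r.uniform(0.5, 1.5, m)
            Q = 0.4 * np.eye(n)
            phi = 0.6
            U = rp.UncertaintyModel(np.eye(m), np.eye(n), np.zeros(n), phi)
            params = rp.RobustSolveParams(lambda_mode="line_search",
                                          search_tolerance=1e-10,
                                          upper_factor=1e4)
            x_rob = rp.robust_ls_solve(A, b, W, Q, U, params).x
            x_nom = rp.robust_ls_solve(A, b, W, Q,
                                       rp.UncertaintyModel(None, None, None, 0.0)).x

            def worst(x):
                s = phi * np.linalg.norm(x)
                best = float(x @ (Q @ x) + ((A @ x - b) ** 2 * W).sum())
                for _ in range(4000):
                    u = r.standard_normal(m)
                    u *= s / np.linalg.norm(u)
                    val = x @ (Q @ x) + (((A @ x - b) + u) ** 2 * W).sum()
                    best = max(best, val)
                return best

            assert worst(x_rob) <= worst(x_nom) + 1e-6


class TestSelectLambda:
    def _instance(self, seed=0):
        r = np.random.default_rng(seed)
        A = r.standard_normal((6, 4))
        b = r.standard_normal(6)
        W = r.uniform(0.5, 2.0, 6)
        Q = 0.2 * np.eye(4)
        U = rp.UncertaintyModel(np.eye(6) * 0.5, np.eye(4), np.zeros(4), 0.5)
        return A, b, W, Q, U

    def test_alpha_zero_returns_lower_bound(self):
        A, b, W, Q, U = self._instance()
        lam = rp.select_lambda(A, b, W, Q, U, rp.RobustSolveParams(alpha=0.0))
        assert lam == pytest.approx(lambda_lower_bound(W, U))

    def test_alpha_shortcut_formula(self):
        A, b, W, Q, U = self._instance()
        lam = rp.select_lambda(A, b, W, Q, U, rp.RobustSolveParams(alpha=0.5))
        assert lam == pytest.approx(1.5 * lambda_lower_bound(W, U))

    def test_line_search_beats_shortcuts(self):
        from robustpet.robust import _g_cost

        A, b, W, Q, U = self._instance(3)
        params = rp.RobustSolveParams(lambda_mode="line_search",
                                      search_tolerance=1e-10)
        lam_star = rp.select_lambda(A, b, W, Q, U, params)
        g_star = _g_cost(A, b, W, Q, U, lam_star)
        lam_l = lambda_lower_bound(W, U)
        for alpha in (0.1, 0.5, 1.0):
            assert g_star <= _g_cost(A, b, W, Q, U, (1 + alpha) * lam_l) + 1e-9
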