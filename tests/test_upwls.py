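"""State-space UPWLS recursion: init, update, correct, full iteration."""

import numpy as np
import pytest
import scipy.sparse as sp

import robustpet as rp
from robustpet.penalty import PenaltyModel

NULL_U = rp.UncertaintyModel(None, None, None, 0.0)


@pytest.fixture()
def toy_problem(toy_geom, toy_D):
    truth = rp.ActivityImage(toy_geom, np.array([1.0, 2.0, 0.5, 1.5]))
    y = rp.Sinogram(toy_geom, toy_D.entries @ truth.values, kind="corrected")
    pen = PenaltyModel(toy_geom, beta=1.0)
    ssm = rp.StateSpaceModel(R=1.0, qv=0.0)
    return truth, y, pen, ssm


class TestInit:
    def test_zero_mode(self, toy_problem, toy_D):
        _, y, pen, ssm = toy_problem
        state = rp.upwls_init(y, toy_D, pen, ssm, x0_mode="zero")
        assert np.all(state.x_hat == 0)

    def test_initial_covariance_inverts_penalty(self):
        geom = rp.ScanGeometry(grid_nx=16, grid_ny=16, n_angles=4, n_bins=23)
        D = rp.build_system_matrix(geom)
        pen = PenaltyModel(geom, beta=1.0)
        y = rp.Sinogram(geom, np.zeros(geom.n_rays), kind="corrected")
        state = rp.upwls_init(y, D, pen, rp.StateSpaceModel(R=1.0))
        prod = state.P @ pen.ridged().toarray()
        np.testing.assert_allclose(prod, np.eye(geom.n_voxels), atol=1e-8)

    def test_fbp_mode_starts_closer(self, small_geom, small_D, small_phantom):
        y = rp.forward_project(small_D, small_phantom)
        yc = rp.Sinogram(small_geom, y.values, kind="corrected")
        pen = PenaltyModel(small_geom, beta=1.0)
        ssm = rp.StateSpaceModel(R=1.0)
        s0 = rp.upwls_init(yc, small_D, pen, ssm, x0_mode="zero")
        s1 = rp.upwls_init(yc, small_D, pen, ssm, x0_mode="fbp")
        e0 = np.linalg.norm(s0.x_hat - small_phantom.values)
        e1 = np.linalg.norm(s1.x_hat - small_phantom.values)
        assert e1 < e0

    def test_bad_mode_raises(self, toy_problem, toy_D):
        _, y, pen, ssm = toy_problem
        with pytest.raises(ValueError):
            rp.upwls_init(y, toy_D, pen, ssm, x0_mode="nope")


class TestUpdate:
    def test_static_noiseless_unchanged(self, toy_problem, toy_D):
        _, y, pen, ssm = toy_problem
        state = rp.upwls_init(y, toy_D, pen, ssm)
        new = rp.upwls_update(state, rp.StateSpaceModel(R=1.0, qv=0.0))
        np.testing.assert_array_equal(new.x_hat, state.x_hat)
        np.testing.assert_array_equal(new.P, state.P)

    def test_process_noise_inflates_exactly(self, toy_problem, toy_D):
        _, y, pen, ssm = toy_problem
        state = rp.upwls_init(y, toy_D, pen, ssm)
        q = 0.07
        new = rp.upwls_update(state, rp.StateSpaceModel(R=1.0, qv=q))
        np.testing.assert_allclose(new.P, state.P + q * np.eye(4), atol=1e-12)

    def test_robust_prediction_dominates_nominal(self, toy_problem, toy_D):
        """Loewner order: prediction under the uncertainty model is >= the
        accurate-model prediction (equality here — the uncertainty enters the
        measurement matrix, not the transition)."""
        _, y, pen, ssm = toy_problem
        U = rp.make_norm_bounded_model(toy_D, 0.06)
        state = rp.upwls_init(y, toy_D, pen, ssm)
        nominal = rp.upwls_update(state, ssm, NULL_U)
        robust = rp.upwls_update(state, ssm, U)
        gap_eigs = np.linalg.eigvalsh(robust.P - nominal.P)
        assert gap_eigs.min() >= -1e-12


class TestCorrect:
    def test_classical_limit_matches_kalman(self, toy_problem, toy_D):
        truth, y, pen, ssm = toy_problem
        state = rp.upwls_init(y, toy_D, pen, ssm)
        Dm = toy_D.entries.toarray()
        P = state.P.copy()
        x = state.x_hat.copy()
        for _ in range(4):
            state = rp.upwls_update(state, ssm, NULL_U)
            state = rp.upwls_correct(state, y, toy_D, NULL_U, ssm)
            Pn = np.linalg.inv(np.linalg.inv(P) + Dm.T @ Dm)
            x = x + Pn @ (Dm.T @ (y.values - Dm @ x))
            P = Pn
            np.testing.assert_allclose(state.x_hat, x, atol=1e-8)
            np.testing.assert_allclose(state.P, P, atol=1e-8)

    def test_perfect_data_epsilon_sweep(self, rng):
        """With y = D x_true, R -> eps I and D square invertible, the first
        correction converges to the truth as eps shrinks."""
        geom = rp.ScanGeometry(grid_nx=2, grid_ny=2, n_angles=2, n_bins=2)
        A = rng.random((4, 4)) + 4 * np.eye(4)
        D = rp.SystemMatrix(geom, sp.csr_matrix(A))
        truth = np.array([1.0, 0.5, 2.0, 1.2])
        y = rp.Sinogram(geom, A @ truth, kind="corrected")
        pen = PenaltyModel(geom, beta=1.0)
        errs = []
        for eps in (1e-1, 1e-3, 1e-5, 1e-7):
            ssm = rp.StateSpaceModel(R=eps)
            state = rp.upwls_init(y, D, pen, ssm)
            state = rp.upwls_correct(state, y, D, NULL_U, ssm)
            errs.append(np.linalg.norm(state.x_hat - truth))
        assert all(np.diff(errs) < 0)
        assert errs[-1] < 1e-5

    def test_information_never_decreases(self, toy_problem, toy_D):
        _, y, pen, ssm = toy_problem
        state = rp.upwls_init(y, toy_D, pen, ssm)
        prior = rp.upwls_update(state, ssm, NULL_U)
        post = rp.upwls_correct(prior, y, toy_D, NULL_U, ssm)
        eigs = np.linalg.eigvalsh(prior.P - post.P)
        assert eigs.min() >= -1e-10


class TestReconstruct:
    def test_noiseless_exact_matrix_converges(self, small_geom, small_D, small_phantom):
        y = rp.Sinogram(small_geom, small_D.entries @ small_phantom.values,
                        kind="corrected", meta={"scale": 1.0})
        pen = PenaltyModel(small_geom, beta=1e-3)
        ssm = rp.StateSpaceModel(R=1.0, qv=0.0)
        res = rp.upwls_reconstruct(
            y, small_D, pen, ssm, NULL_U,
            stop=rp.ConvergenceConfig(epsilon=0.0, max_iter=50),
            x_true=small_phantom, x0_mode="fbp",
        )
        assert res.error_trace[-1] < 0.01

    def test_infinite_epsilon_one_correction(self, toy_problem, toy_D):
        truth, y, pen, ssm = toy_problem
        res = rp.upwls_reconstruct(
            y, toy_D, pen, ssm, NULL_U,
            stop=rp.ConvergenceConfig(epsilon=np.inf, max_iter=100), x_true=truth,
        )
        assert res.n_iter == 1 and res.converged

    def test_fbp_init_reaches_tolerance_faster(self, small_geom, small_D,
                                               small_phantom):
        """With a strong smoothness prior the FBP start needs fewer steps to
        reach a fixed error level than the zero start."""
        y = rp.Sinogram(small_geom, small_D.entries @ small_phantom.values,
                        kind="corrected", meta={"scale": 1.0})
        pen = PenaltyModel(small_geom, beta=1.0)
        ssm = rp.StateSpaceModel(R=1.0, qv=0.0)
        iters = {}
        for mode in ("zero", "fbp"):
            res = rp.upwls_reconstruct(
                y, small_D, pen, ssm, NULL_U,
                stop=rp.ConvergenceConfig(epsilon=0.0, max_iter=25),
                x_true=small_phantom, x0_mode=mode,
            )
            e = np.array(res.error_trace)
            assert np.any(e <= 0.2)
            iters[mode] = int(np.argmax(e <= 0.2)) + 1
        assert iters["fbp"] < iters["zero"]

    def test_batch_matches_single_run(self, small_geom, small_D, small_phantom):
        """The shared-covariance batch path reproduces the per-realization
        recursion bit-for-bit under its stated conditions."""
        y = rp.Sinogram(small_geom, small_D.entries @ small_phantom.values,
                        kind="corrected", meta={"scale": 1.0})
        pen = PenaltyModel(small_geom, beta=1.0)
        ssm = rp.StateSpaceModel(R=1.0, qv=0.0)
        single = rp.upwls_reconstruct(
            y, small_D, pen, ssm, NULL_U,
            stop=rp.ConvergenceConfig(epsilon=0.0, max_iter=6),
            x_true=small_phantom, x0_mode="zero",
        )
        X, errs, n_iter = rp.upwls_reconstruct_batch(
            y.values[None, :], small_D, pen, 1.0, 0.0,
            stop=rp.ConvergenceConfig(epsilon=0.0, max_iter=6),
            x_true=small_phantom,
        )
        np.testing.assert_allclose(X[0], single.image.values, atol=1e-10)

    def test_deterministic(self, toy_problem, toy_D):
        truth, y, pen, ssm = toy_problem
        U = rp.make_norm_bounded_model(toy_D, 0.06)
        runs = [
            rp.upwls_reconstruct(y, toy_D, pen, ssm, U,
                                 stop=rp.ConvergenceConfig(epsilon=0.0, max_iter=5),
                                 x_true=truth).image.values
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0], runs[1])


class TestMonotoneRobustness:
    def test_error_stable_under_growing_matrix_error(self):
        """Mean reconstruction error over seeds stays within a tight band as
        the matrix error grows 0 -> 6 -> 12% (the robust estimator absorbs
        the perturbation)."""
        geom = rp.ScanGeometry(grid_nx=16, grid_ny=16, n_angles=16, n_bins=23)
        D = rp.build_system_matrix(geom)
        truth = rp.shepp_logan_phantom(geom)
        proto = rp.ScanProtocol(total_counts=20_000, n_realizations=2, seed=0)
        pen = PenaltyModel(geom, beta=1.0)
        means = []
        for level in (0.0, 0.06, 0.12):
            errs = []
            for seed in (0, 1, 2):
                Dn = (rp.apply_perturbation(
                    D, rp.perturb_system_matrix(D, level, seed=seed))
                    if level else D)
                p, d = rp.simulate_scan(truth, D,
                                        rp.ScanProtocol(total_counts=20_000,
                                                        n_realizations=2,
                                                        seed=seed), 0)
                corr = rp.correct_sinogram(p, d, proto)
                U = rp.make_norm_bounded_model(Dn, 0.06)
                eta = U.scaled_identity_eta()
                w = 1.0 / (20_000 * 1.8 / geom.n_rays)
                X, e, _ = rp.upwls_reconstruct_batch(
                    corr.values[None, :], Dn, pen, w, eta,
                    stop=rp.ConvergenceConfig(epsilon=0.0, max_iter=10),
                    x_true=truth, scale=corr.meta["scale"],
                )
                errs.append(e[0][-1])
            means.append(np.mean(errs))
        assert max(means) - min(means) < 0.1 * means[0]
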