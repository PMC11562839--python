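import numpy as np
import pytest
from sklearn.linear_model import Lasso

import brilliant as b
from brilliant import solver
from brilliant.objective import PenaltyParams


def _blockset(p_sizes, q_sizes):
    xg = b.GroupStructure.from_sizes(p_sizes)
    yg = b.GroupStructure.from_sizes(q_sizes, group_prefix="Y")
    return b.build_intersection_blocks(xg, yg)


class TestStandardize:
    def test_moments(self, rng):
        X = rng.standard_normal((25, 4)) * 3 + 1
        Y = rng.standard_normal((25, 2)) - 2
        Xs, Ys, _ = solver.standardize(X, Y)
        np.testing.assert_allclose(Xs.sum(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose((Xs**2).sum(axis=0), 1, atol=1e-12)
        np.testing.assert_allclose(Ys.mean(axis=0), 0, atol=1e-12)

    def test_idempotent(self, rng):
        X = rng.standard_normal((25, 4))
        Y = rng.standard_normal((25, 2))
        Xs, Ys, _ = solver.standardize(X, Y)
        Xs2, Ys2, _ = solver.standardize(Xs, Ys)
        np.testing.assert_allclose(Xs2, Xs, atol=1e-12)
        np.testing.assert_allclose(Ys2, Ys, atol=1e-12)

    def test_zero_variance_predictor_named(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 4.2
        with pytest.raises(ValueError, match="flat_one"):
            solver.standardize(X, rng.standard_normal((10, 2)),
                               x_names=["a", "flat_one", "c"])

    def test_back_transform_reproduces_affine_predictions(self, rng):
        # fit on standardized data, back-transform, check held-out predictions
        X = rng.standard_normal((40, 5)) * 2 + 3
        Btrue = rng.standard_normal((5, 2))
        Y = X @ Btrue + 0.1 * rng.standard_normal((40, 2))
        Xs, Ys, sc = solver.standardize(X, Y)
        Bs = np.linalg.lstsq(Xs, Ys, rcond=None)[0]
        B_orig, intercept = sc.coefficients_original(Bs)
        Xnew = rng.standard_normal((7, 5)) * 2 + 3
        pred_std = sc.transform_x(Xnew) @ Bs + sc.y_mean
        pred_orig = Xnew @ B_orig + intercept
        np.testing.assert_allclose(pred_std, pred_orig, atol=1e-10)


class TestZeroGroupTest:
    def test_all_below_lambda1_zeroes_block(self):
        # clamped statistic is 0 <= lambda_g
        assert solver.zero_group_test([0.5, -0.3], lambda1=1.0, lambda_g=0.1, n=1)

    def test_no_penalty_keeps_nonzero_scores(self):
        assert not solver.zero_group_test([0.1], lambda1=0.0, lambda_g=0.0, n=1)

    def test_boundary_inclusive_hand_case(self):
        # |S|/n - lambda1 = (3, 4) -> statistic 5 <= lambda_g = 5
        lam1 = 0.7
        scores = [(lam1 + 3), -(lam1 + 4)]
        assert solver.zero_group_test(scores, lam1, lambda_g=5.0, n=1)
        assert not solver.zero_group_test(scores, lam1, lambda_g=4.999, n=1)

    def test_literal_unclamped_variant(self):
        # negative excesses argue for zeroing under the literal statistic
        scores = [0.0, 0.0]
        assert solver.zero_group_test(scores, 1.0, lambda_g=1.0, n=1, clamped=True)
        assert not solver.zero_group_test(scores, 1.0, lambda_g=1.0, n=1, clamped=False)


class TestUpdateCoefficient:
    def test_soft_threshold_kills_small_scores(self):
        out = solver.update_coefficient(
            S=2.9, xj_norm2=1.0, omega_kk=1.0, lambda1=1.0, lambda2=2.0, n=1,
            rest_norms=[0.0], group_norms=[0.0], weights=[1.0],
        )
        assert out == 0.0

    def test_lasso_case_hand_value(self):
        # S=10, n=1, lambda1=1, lambda2=2, single block with rest norm 0
        out = solver.update_coefficient(
            S=10.0, xj_norm2=1.0, omega_kk=1.0, lambda1=1.0, lambda2=2.0, n=1,
            rest_norms=[0.0], group_norms=[0.0], weights=[1.0],
        )
        assert out == pytest.approx(7.0)
        # one-coordinate oracle: minimize 0.5*w*(b - S/w)^2-ish objective
        grid = np.linspace(-12, 12, 480001)
        vals = 0.5 * grid**2 - 10.0 * grid + 1.0 * np.abs(grid) + 2.0 * np.abs(grid)
        assert grid[np.argmin(vals)] == pytest.approx(7.0, abs=1e-4)

    def test_unpenalized_is_weighted_least_squares_step(self):
        out = solver.update_coefficient(
            S=3.0, xj_norm2=2.0, omega_kk=0.5, lambda1=0.0, lambda2=0.0, n=7,
            rest_norms=[1.0], group_norms=[1.2], weights=[1.0],
        )
        assert out == pytest.approx(3.0 / (2.0 * 0.5))

    def test_group_case_uses_previous_norm_denominator(self):
        out = solver.update_coefficient(
            S=4.0, xj_norm2=1.0, omega_kk=1.0, lambda1=0.5, lambda2=0.25, n=2,
            rest_norms=[1.5], group_norms=[2.0], weights=[3.0],
        )
        expected = (4.0 - 2 * 0.5) / (1.0 + 2 * 0.25 * 3.0 / 2.0)
        assert out == pytest.approx(expected)

    def test_internal_error_on_inconsistent_norms(self):
        with pytest.raises(RuntimeError, match="internal"):
            solver.update_coefficient(
                S=1.0, xj_norm2=1.0, omega_kk=1.0, lambda1=0, lambda2=1, n=1,
                rest_norms=[1.0], group_norms=[0.0], weights=[1.0],
            )


class TestHardThreshold:
    def test_zero_threshold_is_identity(self, rng):
        B = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(solver.hard_threshold(B, 0.0), B)

    def test_keep_large_convention(self):
        B = np.array([[0.5, -0.01]])
        np.testing.assert_array_equal(
            solver.hard_threshold(B, 0.1), np.array([[0.5, 0.0]])
        )

    def test_literal_variant_keeps_small(self):
        B = np.array([[0.5, -0.01]])
        np.testing.assert_array_equal(
            solver.hard_threshold(B, 0.1, literal=True), np.array([[0.0, -0.01]])
        )

    def test_support_monotone_in_threshold(self, rng):
        B = rng.standard_normal((6, 5))
        sizes = [
            int((solver.hard_threshold(B, t) != 0).sum())
            for t in np.linspace(0, 3, 13)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            solver.hard_threshold(np.zeros((1, 1)), -0.1)


class TestFit:
    def test_unpenalized_recovers_least_squares(self, rng):
        n, p, q = 50, 6, 4
        X = rng.standard_normal((n, p))
        Btrue = rng.standard_normal((p, q))
        Y = X @ Btrue
        Xs, Ys, _ = solver.standardize(X, Y)
        bs = _blockset((3, 3), (2, 2))
        fr = solver.fit(Xs, Ys, np.eye(q), bs, PenaltyParams(0, 0),
                        solver.SolverOptions(epsilon=1e-10, max_sweeps=5000))
        Bols = np.linalg.lstsq(Xs, Ys, rcond=None)[0]
        assert fr.converged
        np.testing.assert_allclose(fr.B_hat, Bols, atol=1e-6)

    def test_identity_lambda2_zero_matches_per_response_lasso(self, rng):
        n, p, q = 40, 8, 3
        X = rng.standard_normal((n, p))
        Y = X[:, :2] @ rng.standard_normal((2, q)) + rng.standard_normal((n, q))
        Xs, Ys, _ = solver.standardize(X, Y)
        bs = _blockset((4, 4), (2, 1))
        lam1 = 0.01
        fr = solver.fit(Xs, Ys, np.eye(q), bs, PenaltyParams(lam1, 0.0),
                        solver.SolverOptions(epsilon=1e-12, max_sweeps=50000))
        for k in range(q):
            sk = Lasso(alpha=lam1, fit_intercept=False, tol=1e-14,
                       max_iter=10**6).fit(Xs, Ys[:, k]).coef_
            np.testing.assert_allclose(fr.B_hat[:, k], sk, atol=1e-6)

    def test_python_engine_matches_numba(self, rng):
        n, p, q = 30, 6, 4
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        Xs, Ys, _ = solver.standardize(X, Y)
        bs = _blockset((3, 3), (2, 2))
        pp = PenaltyParams(0.01, 0.02)
        f1 = solver.fit(Xs, Ys, np.eye(q), bs, pp,
                        solver.SolverOptions(epsilon=1e-9, engine="numba"))
        f2 = solver.fit(Xs, Ys, np.eye(q), bs, pp,
                        solver.SolverOptions(epsilon=1e-9, engine="python"))
        np.testing.assert_allclose(f1.B_hat, f2.B_hat, atol=1e-9)
        assert f1.sweeps_run == f2.sweeps_run

    def test_jacobi_variant_converges_on_easy_problem(self, rng):
        n, p, q = 40, 4, 2
        X = rng.standard_normal((n, p))
        Y = X @ np.array([[1.0, 0], [0, -1], [0, 0], [0.5, 0.5]]) \
            + 0.1 * rng.standard_normal((n, q))
        Xs, Ys, _ = solver.standardize(X, Y)
        bs = _blockset((2, 2), (1, 1))
        pp = PenaltyParams(0.005, 0.005)
        gs = solver.fit(Xs, Ys, np.eye(q), bs, pp,
                        solver.SolverOptions(epsilon=1e-10, engine="python"))
        ja = solver.fit(Xs, Ys, np.eye(q), bs, pp,
                        solver.SolverOptions(epsilon=1e-10, engine="python",
                                             update="jacobi", max_sweeps=20000))
        assert ja.converged
        np.testing.assert_allclose(ja.B_hat, gs.B_hat, atol=1e-6)

    def test_nonconvergence_flagged_not_raised(self, rng):
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 4))
        Xs, Ys, _ = solver.standardize(X, Y)
        bs = _blockset((3, 3), (2, 2))
        fr = solver.fit(Xs, Ys, np.eye(4), bs, PenaltyParams(0.0001, 0.0),
                        solver.SolverOptions(epsilon=1e-14, max_sweeps=2))
        assert not fr.converged
        assert fr.sweeps_run == 2

    def test_warm_start_reaches_same_solution(self, rng):
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 4))
        Xs, Ys, _ = solver.standardize(X, Y)
        bs = _blockset((3, 3), (2, 2))
        pp_strong = PenaltyParams(0.02, 0.02)
        pp_weak = PenaltyParams(0.005, 0.005)
        opts = solver.SolverOptions(epsilon=1e-11, max_sweeps=20000)
        cold = solver.fit(Xs, Ys, np.eye(4), bs, pp_weak, opts)
        strong = solver.fit(Xs, Ys, np.eye(4), bs, pp_strong, opts)
        warm = solver.fit(Xs, Ys, np.eye(4), bs, pp_weak, opts, start=strong.B_hat)
        np.testing.assert_allclose(warm.B_hat, cold.B_hat, atol=1e-7)


class TestModelLevelProperties:
    def test_permutation_equivariance_in_responses(self, rng):
        n, p, q = 40, 6, 4
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q)) + X[:, :1]
        xg = b.GroupStructure.from_sizes((3, 3))
        perm = np.array([2, 0, 3, 1])
        yg = b.GroupStructure.from_sizes((2, 2), group_prefix="Y")
        yg_p = b.GroupStructure(
            [f"f{i + 1:04d}" for i in range(q)],
            {g: [int(np.flatnonzero(perm == i)[0]) for i in idx]
             for g, idx in yg.groups.items()},
        )
        A = rng.standard_normal((q, q))
        Om = A @ A.T + np.eye(q)
        Om_p = Om[np.ix_(perm, perm)]
        m1 = b.BrilliantModel(Y, X, x_groups=xg, y_groups=yg, precision=Om)
        m2 = b.BrilliantModel(Y[:, perm], X, x_groups=xg, y_groups=yg_p,
                              precision=Om_p)
        r1 = m1.fit(0.01, 0.01, epsilon=1e-10, max_sweeps=20000)
        r2 = m2.fit(0.01, 0.01, epsilon=1e-10, max_sweeps=20000)
        np.testing.assert_allclose(r2.fit.B_hat, r1.fit.B_hat[:, perm], atol=1e-6)

    def test_predict_on_training_data_equals_fitted_values(self, tiny_structures):
        X, Y, xg, yg, _ = tiny_structures
        m = b.BrilliantModel(Y, X, x_groups=xg, y_groups=yg, precision="block")
        res = m.fit(0.01, 0.01)
        np.testing.assert_allclose(
            res.predict(X).to_numpy(), res.fittedvalues.to_numpy(), atol=1e-12
        )

    def test_predict_zero_model_returns_training_means(self, tiny_structures):
        X, Y, xg, yg, _ = tiny_structures
        m = b.BrilliantModel(Y, X, x_groups=xg, y_groups=yg, precision="identity")
        res = m.fit(10 * m.lambda_max(), 0.0)
        assert (res.fit.B_hat == 0).all()
        pred = res.predict(X.iloc[:5])
        np.testing.assert_allclose(
            pred.to_numpy(), np.tile(Y.mean().to_numpy(), (5, 1)), atol=1e-12
        )

    def test_predict_aligns_columns_by_name(self, tiny_structures):
        X, Y, xg, yg, _ = tiny_structures
        m = b.BrilliantModel(Y, X, x_groups=xg, y_groups=yg)
        res = m.fit(0.01, 0.01)
        shuffled = X.iloc[:4, ::-1]
        np.testing.assert_allclose(
            res.predict(shuffled).to_numpy(), res.predict(X.iloc[:4]).to_numpy()
        )

    def test_predict_reports_missing_and_extra_columns(self, tiny_structures):
        X, Y, xg, yg, _ = tiny_structures
        res = b.BrilliantModel(Y, X, x_groups=xg, y_groups=yg).fit(0.01, 0.01)
        bad = X.rename(columns={"x0": "zz"})
        with pytest.raises(ValueError, match="x0"):
            res.predict(bad)
        with pytest.raises(ValueError, match="zz"):
            res.predict(bad)

    def test_identity_precision_file_equals_builtin(self, tiny_structures, tmp_path):
        import pandas as pd

        X, Y, xg, yg, _ = tiny_structures
        path = tmp_path / "omega.tsv"
        pd.DataFrame(np.eye(4), index=Y.columns, columns=Y.columns).to_csv(
            path, sep="\t"
        )
        r1 = b.BrilliantModel(Y, X, x_groups=xg, y_groups=yg,
                              precision="identity").fit(0.01, 0.02)
        r2 = b.BrilliantModel(Y, X, x_groups=xg, y_groups=yg,
                              precision=str(path)).fit(0.01, 0.02)
        np.testing.assert_array_equal(r1.fit.B_hat, r2.fit.B_hat)

    def test_summary_mentions_convergence_and_sparsity(self, small_model):
        res = small_model.fit(0.01, 0.01)
        text = res.summary()
        assert "converged" in text and "lambda1" in text and "blocks" in text
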