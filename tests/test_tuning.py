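import numpy as np
import pandas as pd
import pytest

import brilliant as b
from brilliant.tuning import (
    CVPlan,
    TuningGrid,
    _dedup_pairs,
    grid_search,
    nested_cv,
)


def _split(sim, name):
    return sim.frames(name)


class TestTuningGrid:
    def test_validation(self):
        with pytest.raises(ValueError, match="empty"):
            TuningGrid(lambda1=(), lambda2=(0.1,))
        with pytest.raises(ValueError, match="negative"):
            TuningGrid(lambda1=(0.1,), lambda2=(-0.1,))

    def test_default_anchored_at_lambda_max(self, small_model):
        grid = TuningGrid.default(small_model)
        lam_max = small_model.lambda_max()
        assert max(grid.lambda1) == pytest.approx(lam_max)
        assert min(grid.lambda1) == pytest.approx(lam_max / 1000)
        assert len(grid.lambda1) == 8 and len(grid.b_thr) == 6
        # the anchor really zeroes the fit
        res = small_model.fit(lam_max * (1 + 1e-9), 0.0)
        assert (res.fit.B_hat == 0).all()

    def test_dedup_orders_strongest_first(self):
        grid = TuningGrid(lambda1=(0.1, 0.1, 0.3), lambda2=(0.2, 0.2))
        pairs = _dedup_pairs(grid)
        assert len(pairs) == 2
        assert pairs[0] == (0.3, 0.2)


class TestGridSearch:
    def test_single_point_grid_returns_it(self, small_sim, small_model):
        Xv, Yv = _split(small_sim, "val")
        grid = TuningGrid(lambda1=(0.01,), lambda2=(0.02,), b_thr=(0.0,))
        gs = grid_search(small_model, Xv, Yv, grid=grid)
        assert gs.best_params["lambda1"] == 0.01
        assert gs.best_params["lambda2"] == 0.02
        assert len(gs.table) == 1

    def test_duplicate_points_fitted_once(self, small_sim, small_model):
        Xv, Yv = _split(small_sim, "val")
        grid = TuningGrid(lambda1=(0.01, 0.01), lambda2=(0.02,), b_thr=(0.0,))
        gs = grid_search(small_model, Xv, Yv, grid=grid)
        assert len(gs.table) == 1

    def test_all_zero_fits_predict_validation_means(self, small_sim, small_model):
        Xv, Yv = _split(small_sim, "val")
        lam = 2 * small_model.lambda_max()
        grid = TuningGrid(lambda1=(lam, 3 * lam), lambda2=(0.0,), b_thr=(0.0,))
        gs = grid_search(small_model, Xv, Yv, grid=grid)
        # mean-only model: MSE equals average squared deviation of validation
        # responses from the training means
        ybar = small_model.Y.mean(axis=0)
        expected = float(((Yv.to_numpy() - ybar) ** 2).mean())
        assert gs.val_mse == pytest.approx(expected, rel=1e-12)
        assert (gs.results.fit.B_tilde == 0).all()

    def test_ties_break_toward_stronger_penalty(self, small_sim, small_model):
        Xv, Yv = _split(small_sim, "val")
        lam = 2 * small_model.lambda_max()
        # both points give the all-zero fit, hence identical scores
        grid = TuningGrid(lambda1=(lam, 4 * lam), lambda2=(0.0,), b_thr=(0.0,))
        gs = grid_search(small_model, Xv, Yv, grid=grid)
        assert gs.best_params["lambda1"] == pytest.approx(4 * lam)

    def test_no_leakage_from_validation(self, small_sim):
        Xtr, Ytr = _split(small_sim, "train")
        Xv, Yv = _split(small_sim, "val")
        grid = TuningGrid(lambda1=(0.01,), lambda2=(0.01,), b_thr=(0.0,))
        m1 = b.BrilliantModel(Ytr, Xtr, x_groups=small_sim.x_groups,
                              y_groups=small_sim.y_groups, precision="block")
        gs1 = grid_search(m1, Xv, Yv, grid=grid)
        # corrupt the held-out data: the fitted coefficients must not move
        m2 = b.BrilliantModel(Ytr, Xtr, x_groups=small_sim.x_groups,
                              y_groups=small_sim.y_groups, precision="block")
        gs2 = grid_search(m2, Xv * 3.0 + 1.0, Yv * -2.0, grid=grid)
        np.testing.assert_array_equal(gs1.results.fit.B_hat, gs2.results.fit.B_hat)

    def test_selected_params_beat_grid_corners_on_test(self, small_sim, small_model):
        # sanity: tuning should not lose to the extreme corners of its grid
        Xv, Yv = _split(small_sim, "val")
        Xte, Yte = _split(small_sim, "test")
        gs = grid_search(small_model, Xv, Yv)
        test_mse = b.mse(Yte.to_numpy(), gs.results.predict(Xte).to_numpy())
        lam_max = small_model.lambda_max()
        corner_mses = []
        for l1, l2 in [(lam_max, lam_max), (lam_max / 100, lam_max / 100)]:
            corner = small_model.fit(l1, l2)
            corner_mses.append(
                b.mse(Yte.to_numpy(), corner.predict(Xte).to_numpy())
            )
        assert test_mse <= min(corner_mses) * 1.05


class TestNestedCV:
    def test_plan_validation(self):
        with pytest.raises(ValueError):
            CVPlan(outer=1)

    def test_deterministic_given_seed(self, small_sim):
        Xtr, Ytr = _split(small_sim, "train")
        grid = TuningGrid(lambda1=(0.02, 0.005), lambda2=(0.01,), b_thr=(0.0,))
        kwargs = dict(
            x_groups=small_sim.x_groups, y_groups=small_sim.y_groups,
            precision="block", grid=grid, plan=CVPlan(outer=3, inner=2, seed=9),
        )
        cv1 = nested_cv(Xtr, Ytr, **kwargs)
        cv2 = nested_cv(Xtr, Ytr, **kwargs)
        pd.testing.assert_frame_equal(cv1.oof_predictions, cv2.oof_predictions)
        assert cv1.fold_params == cv2.fold_params

    def test_every_sample_predicted_out_of_fold(self, small_sim):
        Xtr, Ytr = _split(small_sim, "train")
        grid = TuningGrid(lambda1=(0.01,), lambda2=(0.01,), b_thr=(0.0,))
        cv = nested_cv(
            Xtr, Ytr, x_groups=small_sim.x_groups, y_groups=small_sim.y_groups,
            precision="block", grid=grid, plan=CVPlan(outer=3, inner=2, seed=1),
        )
        assert not cv.oof_predictions.isna().any().any()
        covered = np.concatenate(cv.fold_indices)
        assert len(np.unique(covered)) == len(Xtr)

    def test_null_model_oof_mse_matches_response_variance(self):
        # data simulated with B = 0: out-of-fold MSE ~ total response variance
        cfg = b.SimulationConfig(
            n_train=90, n_val=0, n_test=0,
            x_group_sizes=(5, 5), y_group_sizes=(2, 2),
            nonzero_block_frac=0.0, rho_e=0.3, seed=21,
        )
        sim = b.simulate_dataset(cfg)
        Xtr, Ytr = sim.frames("train")
        grid = TuningGrid(lambda1=(0.05, 0.2), lambda2=(0.05,), b_thr=(0.0,))
        cv = nested_cv(
            Xtr, Ytr, x_groups=sim.x_groups, y_groups=sim.y_groups,
            precision="identity", grid=grid, plan=CVPlan(outer=3, inner=2, seed=2),
        )
        var_total = float(Ytr.to_numpy().var(axis=0).mean())
        assert cv.oof_mse == pytest.approx(var_total, rel=0.25)
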