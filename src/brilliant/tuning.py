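"""Hyperparameter selection: validation grid search and nested cross-validation.

The simulation protocol tunes (lambda1, lambda2, b_thr) by prediction MSE on
a held-out validation set; real-data analyses use 3-fold nested CV, with the
inner folds selecting the penalties and the outer folds producing honest
out-of-fold predictions.  Standardization and working-precision estimation
always happen inside the training portion of a fold, never on held-out
samples.

Fits along the penalty grid are warm-started from strongest to weakest
penalization.  Thresholds are tuned jointly with the penalties at no extra
fitting cost: b_thr only re-zeroes the already-fitted coefficients.  The
default threshold candidates are relative ({0} plus log-spaced fractions of
max|B_hat| of each fit) so that they aggregate coherently across CV folds;
user-supplied candidates are absolute values on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import solver as _solver
from .metrics import mse as _mse
from .model import BrilliantModel, BrilliantResults

__all__ = [
    "TuningGrid",
    "CVPlan",
    "GridSearchResult",
    "NestedCVResult",
    "ConvergenceError",
    "grid_search",
    "nested_cv",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class TuningGrid:
    """Candidate values for lambda1, lambda2 and b_thr (all non-negative,
    non-empty).  ``b_thr_relative`` marks thresholds as fractions of each
    fit's max|B_hat| rather than absolute values."""

    lambda1: tuple
    lambda2: tuple
    b_thr: tuple = (0.0,)
    b_thr_relative: bool = False

    def __post_init__(self):
        self.lambda1 = tuple(float(v) for v in self.lambda1)
        self.lambda2 = tuple(float(v) for v in self.lambda2)
        self.b_thr = tuple(float(v) for v in self.b_thr)
        for name, vals in (("lambda1", self.lambda1), ("lambda2", self.lambda2),
                           ("b_thr", self.b_thr)):
            if len(vals) == 0:
                raise ValueError(f"{name} grid is empty")
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} grid contains negative values")

    @classmethod
    def default(cls, model: BrilliantModel, n_lambda: int = 8,
                floor: float = 1000.0) -> "TuningGrid":
        """lambda grids log-spaced over [lambda_max/floor, lambda_max], where
        lambda_max is the smallest lambda1 zeroing the whole fit; threshold
        candidates {0} plus 5 log-spaced fractions of max|B_hat|.

        The floor of lambda_max/1000 is deliberately deep: with strong
        signals and n close to p the prediction-optimal penalty sits 2-3
        decades below lambda_max, and a shallower grid leaves the argmin
        pinned at the boundary.
        """
        lam_max = model.lambda_max()
        lams = tuple(np.geomspace(lam_max / floor, lam_max, n_lambda))
        bthr = (0.0,) + tuple(np.geomspace(1e-3, 0.3, 5))
        return cls(lambda1=lams, lambda2=lams, b_thr=bthr, b_thr_relative=True)


@dataclass
class CVPlan:
    """Nested CV layout: outer folds produce predictions, inner folds pick
    the penalties; the seed fixes both fold assignments."""

    outer: int = 3
    inner: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.outer < 2 or self.inner < 2:
            raise ValueError("outer and inner fold counts must be >= 2")


def _dedup_pairs(grid: TuningGrid):
    """Unique (lambda1, lambda2) pairs, strongest penalization first."""
    pairs = sorted(
        {(l1, l2) for l1 in grid.lambda1 for l2 in grid.lambda2},
        key=lambda t: (-(t[0] + t[1]), -t[0], -t[1]),
    )
    return pairs


def _align_validation(model: BrilliantModel, X_val, Y_val):
    if isinstance(X_val, pd.DataFrame):
        missing = sorted(set(model.x_names) - set(map(str, X_val.columns)))
        if missing:
            raise ValueError("validation X lacks predictors: " + ", ".join(missing[:10]))
        X_val = X_val.loc[:, model.x_names].to_numpy(dtype=float)
    else:
        X_val = np.asarray(X_val, dtype=float)
    if isinstance(Y_val, pd.DataFrame):
        Y_val = Y_val.loc[:, model.y_names].to_numpy(dtype=float)
    else:
        Y_val = np.asarray(Y_val, dtype=float)
    return X_val, Y_val


def _score_grid(model: BrilliantModel, X_val, Y_val, grid: TuningGrid,
                options: _solver.SolverOptions | None) -> pd.DataFrame:
    """Fit every penalty pair (warm-started) and score every threshold
    candidate on the validation data.  One row per grid point."""
    X_val, Y_val = _align_validation(model, X_val, Y_val)
    Xs_val = model.scaler.transform_x(X_val)
    rows = []
    start = None
    for lam1, lam2 in _dedup_pairs(grid):
        res = model.fit(lam1, lam2, start=start, options=options)
        start = res.fit.B_hat
        scale = float(np.abs(res.fit.B_hat).max())
        for b in grid.b_thr:
            b_abs = b * scale if grid.b_thr_relative else b
            B_t = _solver.hard_threshold(res.fit.B_hat, b_abs)
            Yhat = Xs_val @ B_t + model.scaler.y_mean
            rows.append(
                {
                    "lambda1": lam1,
                    "lambda2": lam2,
                    "b_key": b,
                    "b_thr": b_abs,
                    "mse": _mse(Y_val, Yhat),
                    "converged": res.converged,
                    "sweeps": res.n_sweeps,
                }
            )
    table = pd.DataFrame(rows)
    if not table["converged"].any():
        raise ConvergenceError(
            "no grid fit converged; sweep counts: "
            + ", ".join(str(s) for s in table["sweeps"].unique())
            + " — raise max_sweeps or epsilon"
        )
    return table


def _select_best(table: pd.DataFrame) -> pd.Series:
    """argmin of MSE; exact ties broken toward larger lambda1, then
    lambda2, then b_thr."""
    ranked = table.sort_values(
        by=["mse", "lambda1", "lambda2", "b_key"],
        ascending=[True, False, False, False],
        kind="mergesort",
    )
    return ranked.iloc[0]


@dataclass
class GridSearchResult:
    best_params: dict
    table: pd.DataFrame
    results: BrilliantResults
    val_mse: float


def grid_search(
    model: BrilliantModel,
    X_val,
    Y_val,
    grid: TuningGrid | None = None,
    options: _solver.SolverOptions | None = None,
    refit_from_zero: bool = False,
) -> GridSearchResult:
    """Select (lambda1, lambda2, b_thr) by validation MSE.

    ``model`` is built from the training data only; ``X_val``/``Y_val`` are
    used solely for scoring.  Returns the score table, the winning
    parameters, and the model refit at them (thresholded).
    """
    grid = grid or TuningGrid.default(model)
    table = _score_grid(model, X_val, Y_val, grid, options)
    best = _select_best(table)
    start = None
    if not refit_from_zero:
        # replay the warm-started path up to the winning pair
        for lam1, lam2 in _dedup_pairs(grid):
            res = model.fit(lam1, lam2, start=start, options=options)
            start = res.fit.B_hat
            if (lam1, lam2) == (best["lambda1"], best["lambda2"]):
                break
    final = model.fit(
        best["lambda1"], best["lambda2"], b_thr=float(best["b_thr"]),
        start=start, options=options,
    )
    params = {
        "lambda1": float(best["lambda1"]),
        "lambda2": float(best["lambda2"]),
        "b_thr": float(best["b_thr"]),
    }
    return GridSearchResult(
        best_params=params, table=table, results=final, val_mse=float(best["mse"])
    )


@dataclass
class NestedCVResult:
    oof_predictions: pd.DataFrame
    fold_params: list[dict]
    oof_mse: float
    fold_indices: list[np.ndarray]


def nested_cv(
    X,
    Y,
    *,
    x_groups,
    y_groups,
    precision="block",
    grid: TuningGrid | None = None,
    plan: CVPlan | None = None,
    options: _solver.SolverOptions | None = None,
    **model_kwargs,
) -> NestedCVResult:
    """Nested cross-validation: inner folds pick the penalties, outer folds
    generate out-of-fold predictions.

    Deterministic given ``plan.seed``.  Every sample appears in exactly one
    outer test fold; the prediction for it comes from a model that never saw
    it during fitting or tuning.
    """
    plan = plan or CVPlan()
    X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    Y_df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, dtype=float))
    n = len(X_df)
    if n < plan.outer:
        raise ValueError("fewer samples than outer folds")
    if n // plan.outer < 2:
        raise ValueError("an outer fold would contain fewer than 2 samples")

    outer = KFold(n_splits=plan.outer, shuffle=True, random_state=plan.seed)
    oof = pd.DataFrame(np.nan, index=Y_df.index, columns=Y_df.columns, dtype=float)
    fold_params: list[dict] = []
    fold_indices: list[np.ndarray] = []

    for fold, (tr, te) in enumerate(outer.split(X_df)):
        Xtr, Ytr = X_df.iloc[tr], Y_df.iloc[tr]
        inner = KFold(n_splits=plan.inner, shuffle=True, random_state=plan.seed + 1 + fold)
        tables = []
        the_grid = grid
        for itr, ival in inner.split(Xtr):
            m = BrilliantModel(
                Ytr.iloc[itr], Xtr.iloc[itr],
                x_groups=x_groups, y_groups=y_groups, precision=precision,
                **model_kwargs,
            )
            g = the_grid or TuningGrid.default(m)
            if the_grid is None:
                the_grid = g  # same candidate set across inner folds
            tables.append(_score_grid(m, Xtr.iloc[ival], Ytr.iloc[ival], g, options))
        mean_scores = (
            pd.concat(tables)
            .groupby(["lambda1", "lambda2", "b_key"], as_index=False)
            .agg(mse=("mse", "mean"), b_thr=("b_thr", "mean"), converged=("converged", "any"))
        )
        best = _select_best(mean_scores)

        refit_model = BrilliantModel(
            Ytr, Xtr, x_groups=x_groups, y_groups=y_groups, precision=precision,
            **model_kwargs,
        )
        res = refit_model.fit(best["lambda1"], best["lambda2"], options=options)
        b_abs = (
            float(best["b_key"]) * float(np.abs(res.fit.B_hat).max())
            if (the_grid.b_thr_relative)
            else float(best["b_key"])
        )
        B_t = _solver.hard_threshold(res.fit.B_hat, b_abs)
        Xs_te = refit_model.scaler.transform_x(X_df.iloc[te].to_numpy(dtype=float))
        oof.iloc[te] = Xs_te @ B_t + refit_model.scaler.y_mean
        fold_params.append(
            {
                "fold": fold,
                "lambda1": float(best["lambda1"]),
                "lambda2": float(best["lambda2"]),
                "b_thr": b_abs,
                "inner_mse": float(best["mse"]),
            }
        )
        fold_indices.append(np.asarray(te))

    oof_mse = _mse(Y_df.to_numpy(dtype=float), oof.to_numpy(dtype=float))
    return NestedCVResult(
        oof_predictions=oof, fold_params=fold_params,
        oof_mse=oof_mse, fold_indices=fold_indices,
    )
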