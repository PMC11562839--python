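"""Model/Results interface for group-guided penalized multivariate regression.

``BrilliantModel`` is constructed from training data plus the two grouping
structures and a working-precision specification; its :meth:`fit` runs the
mixed coordinate descent at given penalties and returns a
``BrilliantResults`` carrying standardized and original-scale coefficients,
convergence diagnostics, prediction, and a text summary.

Example
-------
>>> from brilliant import BrilliantModel, SimulationConfig, simulate_dataset
>>> sim = simulate_dataset(SimulationConfig(x_group_sizes=(10,)*2,
...                                         y_group_sizes=(3,)*2,
...                                         n_train=50, n_val=20, n_test=20))
>>> Xtr, Ytr = sim.split("train")
>>> model = BrilliantModel(Ytr, Xtr, x_groups=sim.x_groups,
...                        y_groups=sim.y_groups, precision="block")
>>> res = model.fit(lambda1=0.05, lambda2=0.05)
>>> res.converged
True
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import solver as _solver
from .groups import GroupStructure, BlockSet, build_intersection_blocks
from .objective import PenaltyParams, penalized_objective, kkt_residual
from .precision import (
    WorkingPrecision,
    block_diagonal_precision,
    identity_precision,
    load_user_precision,
)

__all__ = ["BrilliantModel", "BrilliantResults"]


def _as_matrix(data, names, what):
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns], list(map(str, data.index))
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be 2-dimensional")
    if names is None:
        prefix = "x" if what == "exog" else "y"
        names = [f"{prefix}{i + 1}" for i in range(arr.shape[1])]
    return arr, [str(c) for c in names], None


def _as_group_structure(spec, labels, what) -> GroupStructure:
    if isinstance(spec, GroupStructure):
        if spec.labels != list(labels):
            if set(spec.labels) == set(labels):
                remap = {
                    g: [spec.labels[i] for i in idx] for g, idx in spec.groups.items()
                }
                return GroupStructure(labels, remap)
            raise ValueError(f"{what} grouping labels do not match the data columns")
        return spec
    if isinstance(spec, dict):
        return GroupStructure(labels, spec)
    if spec is None:
        return GroupStructure(labels, {"all": list(range(len(labels)))})
    return GroupStructure.from_tsv(spec, labels)  # path-like


class BrilliantModel:
    """Penalized multivariate multiple regression with grouped predictors,
    grouped responses, and a working precision matrix on the responses.

    Parameters
    ----------
    endog
        Response matrix Y, n x q (array or DataFrame).
    exog
        Predictor matrix X, n x p (array or DataFrame).
    x_groups, y_groups
        Grouping structures (``GroupStructure``, ``{group: members}`` dict,
        a membership TSV path, or None for a single all-encompassing group).
    precision
        ``"block"`` (default) estimates a block-diagonal working precision
        by inverting within-response-group sample covariances of the
        centered training responses; ``"identity"`` uses the identity
        (reducing the fit to the unweighted MSGLasso-style objective);
        a ``WorkingPrecision``, square array, or TSV path supplies it
        directly.
    weights
        Optional per-block weights w_g (default sqrt of block entry count).
    """

    def __init__(
        self,
        endog,
        exog,
        *,
        x_groups=None,
        y_groups=None,
        precision="block",
        weights=None,
        ridge=None,
        cov_ddof: int = 0,
        x_names=None,
        y_names=None,
    ):
        # arrays without explicit names adopt the grouping's labels
        if y_names is None and not isinstance(endog, pd.DataFrame) and isinstance(y_groups, GroupStructure):
            y_names = y_groups.labels
        if x_names is None and not isinstance(exog, pd.DataFrame) and isinstance(x_groups, GroupStructure):
            x_names = x_groups.labels
        Y, ynames, yindex = _as_matrix(endog, y_names, "endog")
        X, xnames, xindex = _as_matrix(exog, x_names, "exog")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("endog and exog have different numbers of samples")
        if xindex is not None and yindex is not None and xindex != yindex:
            raise ValueError(
                "endog and exog sample IDs differ; align them first "
                "(see brilliant.io.align)"
            )
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("missing or non-finite values in the input matrices")
        self.x_names, self.y_names = xnames, ynames
        self.sample_ids = xindex or yindex
        self.X, self.Y = X, Y
        self.nobs, self.n_predictors = X.shape
        self.n_responses = Y.shape[1]

        self.x_groups = _as_group_structure(x_groups, xnames, "predictor")
        self.y_groups = _as_group_structure(y_groups, ynames, "response")
        self.blocks: BlockSet = build_intersection_blocks(
            self.x_groups, self.y_groups, weights=weights
        )

        self.Xs, self.Ys, self.scaler = _solver.standardize(X, Y, x_names=xnames)
        self.omega = self._resolve_precision(precision, ridge, cov_ddof)

    # ------------------------------------------------------------------
    def _resolve_precision(self, spec, ridge, ddof) -> WorkingPrecision:
        if isinstance(spec, WorkingPrecision):
            if spec.q != self.n_responses:
                raise ValueError("precision matrix size does not match responses")
            return spec
        if isinstance(spec, str):
            if spec == "identity":
                return identity_precision(self.n_responses)
            if spec == "block":
                return block_diagonal_precision(
                    self.Ys, self.y_groups, ridge=ridge, ddof=ddof
                )
            return load_user_precision(spec, self.y_names)
        if spec is None:
            return identity_precision(self.n_responses)
        return WorkingPrecision(np.asarray(spec, dtype=float), source="user_supplied",
                                names=self.y_names)

    def lambda_max(self) -> float:
        """Smallest lambda1 for which the lasso-only fit is entirely zero:
        max_jk |x_j' Y Omega_.k| / n on the standardized scale."""
        S = self.Xs.T @ self.Ys @ self.omega.matrix
        return float(np.abs(S).max() / self.nobs)

    # ------------------------------------------------------------------
    def fit(
        self,
        lambda1: float,
        lambda2: float,
        b_thr: float = 0.0,
        *,
        epsilon: float = 1e-4,
        max_sweeps: int = 1000,
        start: np.ndarray | None = None,
        options: _solver.SolverOptions | None = None,
    ) -> "BrilliantResults":
        """Fit at one penalty setting; returns a :class:`BrilliantResults`."""
        pp = PenaltyParams(lambda1=lambda1, lambda2=lambda2, b_thr=b_thr)
        opts = options or _solver.SolverOptions(epsilon=epsilon, max_sweeps=max_sweeps)
        fr = _solver.fit(self.Xs, self.Ys, self.omega, self.blocks, pp, opts, start=start)
        return BrilliantResults(self, fr)

    def fit_path(self, penalty_pairs, b_thr=0.0, **kwargs):
        """Fit a sequence of (lambda1, lambda2) pairs with warm starts,
        yielding a results object per pair.  Pairs should be ordered from
        strongest to weakest penalization for effective warm starting."""
        start = None
        for lam1, lam2 in penalty_pairs:
            res = self.fit(lam1, lam2, b_thr=b_thr, start=start, **kwargs)
            start = res.fit.B_hat
            yield res

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"BrilliantModel(n={self.nobs}, p={self.n_predictors}, "
            f"q={self.n_responses}, P={self.x_groups.n_groups}, "
            f"Q={self.y_groups.n_groups}, precision={self.omega.source})"
        )


class BrilliantResults:
    """Estimates, diagnostics, prediction and summary for one fitted model."""

    def __init__(self, model: BrilliantModel, fit: _solver.FitResult):
        self.model = model
        self.fit = fit

    # -- coefficient views ---------------------------------------------
    @property
    def coef_standardized(self) -> pd.DataFrame:
        """B_hat on the standardized scale (unit-L2 predictors)."""
        return pd.DataFrame(self.fit.B_hat, index=self.model.x_names,
                            columns=self.model.y_names)

    @property
    def coef_thresholded(self) -> pd.DataFrame:
        """B_tilde: B_hat after hard thresholding at b_thr."""
        return pd.DataFrame(self.fit.B_tilde, index=self.model.x_names,
                            columns=self.model.y_names)

    @property
    def params(self) -> pd.DataFrame:
        """Original-scale coefficients (from B_tilde) with an intercept row."""
        B_orig, intercept = self.model.scaler.coefficients_original(self.fit.B_tilde)
        out = pd.DataFrame(B_orig, index=self.model.x_names, columns=self.model.y_names)
        out.loc["(intercept)"] = intercept
        return out.reindex(["(intercept)"] + self.model.x_names)

    @property
    def params_unthresholded(self) -> pd.DataFrame:
        B_orig, intercept = self.model.scaler.coefficients_original(self.fit.B_hat)
        out = pd.DataFrame(B_orig, index=self.model.x_names, columns=self.model.y_names)
        out.loc["(intercept)"] = intercept
        return out.reindex(["(intercept)"] + self.model.x_names)

    # -- diagnostics ----------------------------------------------------
    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def n_sweeps(self) -> int:
        return self.fit.sweeps_run

    @property
    def final_delta(self) -> float:
        return self.fit.final_delta

    @property
    def objective_trace(self) -> list[float]:
        return list(self.fit.objective_trace)

    def objective(self) -> float:
        return penalized_objective(
            self.model.Xs, self.model.Ys, self.fit.B_hat,
            self.model.omega, self.fit.penalties, self.model.blocks,
        )

    def kkt_violation(self) -> float:
        """Largest stationarity violation of the penalized objective at
        B_hat (0 at an exact optimum)."""
        return kkt_residual(
            self.model.Xs, self.model.Ys, self.fit.B_hat,
            self.model.omega, self.fit.penalties, self.model.blocks,
        )

    def selected_support(self) -> pd.DataFrame:
        return self.coef_thresholded != 0.0

    def block_summary(self) -> pd.DataFrame:
        rows = []
        for g, blk in enumerate(self.model.blocks.blocks):
            sub = self.fit.B_tilde[np.ix_(blk.rows, blk.cols)]
            rows.append(
                {
                    "block": blk.name,
                    "entries": blk.size,
                    "nonzero": int((sub != 0).sum()),
                    "norm": float(np.sqrt((sub * sub).sum())),
                    "weight": float(self.model.blocks.weights[g]),
                }
            )
        return pd.DataFrame(rows).set_index("block")

    # -- prediction -----------------------------------------------------
    def predict(self, exog, use_threshold: bool = True) -> pd.DataFrame:
        """Predict responses for new samples.

        Columns of ``exog`` are aligned to the training predictors by name
        (DataFrame input); missing or extra columns raise.  Prediction uses
        B_tilde by default, or B_hat with ``use_threshold=False``.
        """
        if isinstance(exog, pd.DataFrame):
            cols = [str(c) for c in exog.columns]
            missing = sorted(set(self.model.x_names) - set(cols))
            extra = sorted(set(cols) - set(self.model.x_names))
            if missing or extra:
                msg = []
                if missing:
                    msg.append("missing predictors: " + ", ".join(missing[:10]))
                if extra:
                    msg.append("unknown predictors: " + ", ".join(extra[:10]))
                raise ValueError("; ".join(msg))
            index = exog.index
            Xn = exog.loc[:, self.model.x_names].to_numpy(dtype=float)
        else:
            Xn = np.asarray(exog, dtype=float)
            if Xn.shape[1] != self.model.n_predictors:
                raise ValueError("exog has the wrong number of predictors")
            index = pd.RangeIndex(Xn.shape[0])
        B = self.fit.B_tilde if use_threshold else self.fit.B_hat
        Xs = self.model.scaler.transform_x(Xn)
        Yhat = Xs @ B + self.model.scaler.y_mean
        return pd.DataFrame(Yhat, index=index, columns=self.model.y_names)

    @property
    def fittedvalues(self) -> pd.DataFrame:
        idx = self.model.sample_ids or pd.RangeIndex(self.model.nobs)
        return pd.DataFrame(
            self.model.Xs @ self.fit.B_tilde + self.model.scaler.y_mean,
            index=idx, columns=self.model.y_names,
        )

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        m, f = self.model, self.fit
        nz_hat = int((f.B_hat != 0).sum())
        nz_til = int((f.B_tilde != 0).sum())
        nz_blocks = sum(
            1
            for blk in m.blocks.blocks
            if (f.B_tilde[np.ix_(blk.rows, blk.cols)] != 0).any()
        )
        lines = [
            "Group-guided penalized multivariate regression",
            "=" * 54,
            f"samples            {m.nobs:>8d}    predictors      {m.n_predictors:>8d}",
            f"responses          {m.n_responses:>8d}    blocks (P x Q)  "
            f"{m.x_groups.n_groups:>3d} x {m.y_groups.n_groups:<3d}",
            f"precision source   {m.omega.source:>20s}",
            "-" * 54,
            f"lambda1            {f.penalties.lambda1:>12.6g}",
            f"lambda2            {f.penalties.lambda2:>12.6g}",
            f"b_thr              {f.penalties.b_thr:>12.6g}",
            f"sweeps             {f.sweeps_run:>8d}    converged       {str(f.converged):>8s}",
            f"final delta        {f.final_delta:>12.4e}",
        ]
        if f.objective_trace:
            lines.append(f"objective          {f.objective_trace[-1]:>12.6g}")
        lines += [
            "-" * 54,
            f"nonzero in B_hat   {nz_hat:>8d} / {f.B_hat.size}",
            f"nonzero in B_tilde {nz_til:>8d} / {f.B_tilde.size}",
            f"active blocks      {nz_blocks:>8d} / {m.blocks.G}",
            "=" * 54,
        ]
        return "\n".join(lines)

    def plot_coefficients(self, ax=None, threshold: bool = True):
        """Heatmap of the (thresholded) coefficient matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        B = self.fit.B_tilde if threshold else self.fit.B_hat
        vmax = np.abs(B).max() or 1.0
        im = ax.imshow(B, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xlabel("responses")
        ax.set_ylabel("predictors")
        ax.figure.colorbar(im, ax=ax, label="coefficient")
        return ax

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"<BrilliantResults converged={self.converged} "
            f"sweeps={self.n_sweeps} nnz={int((self.fit.B_tilde != 0).sum())}>"
        )
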