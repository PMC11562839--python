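"""Mixed coordinate descent for the sparse-group penalized multivariate fit.

The solver minimizes the objective of :mod:`brilliant.objective` by sweeping
the coefficient matrix in row-major order.  Each sweep first applies an
exact zero-group screen per intersection block (if the block-KKT condition
for a zero block holds, the whole block is set to exact zeros), then updates
the remaining coordinates with closed-form moves that depend on the status
of the blocks containing the coordinate:

* all containing blocks otherwise zero  -> soft-threshold (Lasso) step with
  threshold n*lambda1 + n*lambda2*sum w_g;
* all containing blocks otherwise nonzero -> ridge-like step whose
  denominator carries n*lambda2*w_g/||B_g|| (a majorization of the group
  norm at the previous iterate, hence monotone);
* mixed -> Lasso-style numerator over the group-style denominator.

Coordinates are soft-thresholded to exact 0.0, so supports are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .groups import BlockSet
from .objective import PenaltyParams, penalized_objective
from .precision import WorkingPrecision

__all__ = [
    "SolverOptions",
    "Scaler",
    "FitResult",
    "standardize",
    "zero_group_test",
    "update_coefficient",
    "hard_threshold",
    "fit",
]


@dataclass
class SolverOptions:
    """Convergence and engine settings.

    epsilon is the threshold on the sup-norm coefficient change per sweep;
    ``engine`` selects the compiled kernel ("numba", default) or the plain
    NumPy mirror ("python"); ``update`` chooses Gauss-Seidel (scores always
    use the latest coefficients) or the Jacobi variant (scores frozen at the
    sweep start; python engine only, provided for comparison).
    """

    epsilon: float = 1e-4
    max_sweeps: int = 1000
    engine: str = "numba"
    update: str = "gauss-seidel"
    clamp_zero_stat: bool = True
    literal_threshold: bool = False
    track_objective: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.engine not in ("numba", "python"):
            raise ValueError("engine must be 'numba' or 'python'")
        if self.update not in ("gauss-seidel", "jacobi"):
            raise ValueError("update must be 'gauss-seidel' or 'jacobi'")
        if self.update == "jacobi" and self.engine == "numba":
            raise ValueError("the jacobi update is available with engine='python'")


@dataclass
class Scaler:
    """Centering/scaling records of :func:`standardize`.

    X columns are centered and scaled to unit L2 norm (sum of squares 1);
    Y columns are centered only.
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray

    def transform_x(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale

    def transform_y(self, Y) -> np.ndarray:
        return np.asarray(Y, dtype=float) - self.y_mean

    def coefficients_original(self, B_std: np.ndarray):
        """Back-transform standardized-scale coefficients; returns
        (B_original, intercept_row)."""
        B_orig = B_std / self.x_scale[:, None]
        intercept = self.y_mean - self.x_mean @ B_orig
        return B_orig, intercept


def standardize(X, Y, x_names=None):
    """Center X and Y; scale X columns to unit L2 norm.

    Returns (Xs, Ys, Scaler).  A predictor with zero variance cannot be
    scaled and raises, naming the column.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-d with matching sample counts")
    if X.shape[0] < 2:
        raise ValueError("standardization needs n >= 2")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    x_scale = np.sqrt((Xc * Xc).sum(axis=0))
    bad = np.flatnonzero(x_scale <= 1e-10 * np.maximum(1.0, np.abs(x_mean)))
    if bad.size:
        name = x_names[bad[0]] if x_names is not None else f"column {bad[0]}"
        raise ValueError(f"predictor {name} has zero variance and cannot be standardized")
    y_mean = Y.mean(axis=0)
    return Xc / x_scale, Y - y_mean, Scaler(x_mean, x_scale, y_mean)


def zero_group_test(scores, lambda1: float, lambda_g: float, n: int, clamped: bool = True) -> bool:
    """Block-KKT screen: True when sqrt(sum ((|S|/n - lambda1)_+)^2) <= lambda_g.

    ``scores`` are the partial scores S_jk over the block's entries with the
    block zeroed.  With ``clamped=False`` the literal (unclamped) statistic
    is used instead.
    """
    t = np.abs(np.asarray(scores, dtype=float)) / n - lambda1
    if clamped:
        t = np.maximum(t, 0.0)
    return bool(np.sqrt(float(t @ t)) <= lambda_g)


def update_coefficient(
    S: float,
    xj_norm2: float,
    omega_kk: float,
    lambda1: float,
    lambda2: float,
    n: int,
    rest_norms,
    group_norms,
    weights,
) -> float:
    """One mixed coordinate-descent move for a single coefficient.

    ``rest_norms[g]`` is ||B_g - (jk)|| (the containing block's norm with
    this entry removed); ``group_norms[g]`` is the full previous-iterate
    block norm used in the group-style denominator; ``weights`` are the
    block weights w_g.  Blocks with zero rest-norm contribute to the
    soft-threshold, the others to the denominator.
    """
    thr = n * lambda1
    den = xj_norm2 * omega_kk
    for r, gnm, wg in zip(rest_norms, group_norms, weights):
        if r == 0.0:
            thr += n * lambda2 * wg
        else:
            if gnm <= 0.0:
                raise RuntimeError(
                    "internal error: block classified nonzero has zero norm"
                )
            den += n * lambda2 * wg / gnm
    a = abs(S) - thr
    if a <= 0.0:
        return 0.0
    return math.copysign(a / den, S)


def hard_threshold(B_hat: np.ndarray, b_thr: float, literal: bool = False) -> np.ndarray:
    """Post-fit hard thresholding producing B_tilde.

    Default keeps coefficients with |b| >= b_thr and zeroes the rest (the
    false-positive filter).  ``literal=True`` applies the opposite
    indicator 1(|b| < b_thr) instead.
    """
    if b_thr < 0:
        raise ValueError("b_thr must be non-negative")
    B_hat = np.asarray(B_hat, dtype=float)
    if b_thr == 0.0:
        return B_hat.copy()
    keep = np.abs(B_hat) < b_thr if literal else np.abs(B_hat) >= b_thr
    return np.where(keep, B_hat, 0.0)


@dataclass
class FitResult:
    """Solver output on the standardized scale plus diagnostics."""

    B_hat: np.ndarray
    B_tilde: np.ndarray
    sweeps_run: int
    final_delta: float
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    penalties: PenaltyParams | None = None
    options: SolverOptions | None = None


def _omega_matrix(omega):
    return omega.matrix if isinstance(omega, WorkingPrecision) else np.asarray(omega, float)


def fit(
    Xs,
    Ys,
    omega,
    bs: BlockSet,
    pp: PenaltyParams,
    opts: SolverOptions | None = None,
    start: np.ndarray | None = None,
) -> FitResult:
    """Run the mixed coordinate descent on standardized inputs.

    ``start`` warm-starts from a previous solution (standardized scale);
    the default start is the zero matrix.  Non-convergence at max_sweeps is
    reported through ``converged=False``, not raised.
    """
    opts = opts or SolverOptions()
    Xs = np.ascontiguousarray(Xs, dtype=float)
    Ys = np.ascontiguousarray(Ys, dtype=float)
    Om = np.ascontiguousarray(_omega_matrix(omega))
    n, p = Xs.shape
    q = Ys.shape[1]
    if bs.n_predictors != p or bs.n_responses != q:
        raise ValueError("block set does not match the data dimensions")
    if Om.shape != (q, q):
        raise ValueError("precision matrix does not match the number of responses")

    B = np.zeros((p, q)) if start is None else np.array(start, dtype=float, copy=True)
    XtX = Xs.T @ Xs
    XtR = Xs.T @ Ys - XtX @ B

    br_ptr, br_idx = bs.rows_csr()
    bc_ptr, bc_idx = bs.cols_csr()
    memb_ptr, memb_idx = bs.membership_csr()
    w = np.ascontiguousarray(bs.weights, dtype=float)
    nnz = np.zeros(bs.G, dtype=np.int64)
    gnorm2 = np.zeros(bs.G)
    active = np.ones(bs.G, dtype=np.bool_)

    # per-block step sizes 1/L_g for the proximal activation move;
    # L_g bounds the block's smooth-loss curvature
    tstep = np.empty(bs.G)
    for g, blk in enumerate(bs.blocks):
        lx = float(np.linalg.eigvalsh(XtX[np.ix_(blk.rows, blk.rows)]).max())
        lo = float(np.linalg.eigvalsh(Om[np.ix_(blk.cols, blk.cols)]).max())
        prod = lx * lo
        tstep[g] = n / prod if prod > 0 else 0.0

    if opts.engine == "numba":
        from ._kernels import sweep_gauss_seidel as sweep

        def run_sweep():
            return sweep(
                XtX, XtR, Om, B, float(n), pp.lambda1, pp.lambda2, w,
                br_ptr, br_idx, bc_ptr, bc_idx, memb_ptr, memb_idx,
                nnz, gnorm2, active, opts.clamp_zero_stat, tstep,
            )

    else:
        from ._pysweep import sweep_python

        def run_sweep():
            return sweep_python(
                XtX, XtR, Om, B, n, pp.lambda1, pp.lambda2, w,
                bs, nnz, gnorm2, active, opts.clamp_zero_stat,
                tstep=tstep, jacobi=(opts.update == "jacobi"),
            )

    trace: list[float] = []
    if opts.track_objective:
        trace.append(penalized_objective(Xs, Ys, B, Om, pp, bs))

    delta = np.inf
    sweeps = 0
    converged = False
    while sweeps < opts.max_sweeps:
        delta = float(run_sweep())
        sweeps += 1
        if opts.track_objective:
            trace.append(penalized_objective(Xs, Ys, B, Om, pp, bs))
        if delta <= opts.epsilon:
            converged = True
            break

    B_tilde = hard_threshold(B, pp.b_thr, literal=opts.literal_threshold)
    return FitResult(
        B_hat=B,
        B_tilde=B_tilde,
        sweeps_run=sweeps,
        final_delta=delta,
        objective_trace=trace,
        converged=converged,
        penalties=pp,
        options=opts,
    )
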