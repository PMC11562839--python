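"""The penalized objective and its coordinate-wise score.

objective(B) = tr((Y - XB)' (Y - XB) Omega) / (2n)
             + lambda1 * sum_jk |b_jk|
             + lambda2 * sum_g w_g * ||B_g||_2

The partial score S_jk = x_j' (Y - X B_(-jk)) Omega_.k (B_(-jk) has entry
(j,k) zeroed) drives every coordinate update of the solver; the same
quantities are exposed here so tests can check the solver against them
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .groups import BlockSet
from .precision import WorkingPrecision

__all__ = [
    "PenaltyParams",
    "penalized_objective",
    "partial_score",
    "group_norms",
    "kkt_residual",
]


@dataclass
class PenaltyParams:
    """Non-negative tuning parameters: lambda1 (elementwise Lasso),
    lambda2 (group Lasso, multiplied per block by the block weight w_g) and
    the post-fit hard threshold b_thr."""

    lambda1: float
    lambda2: float
    b_thr: float = 0.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0 or self.b_thr < 0:
            raise ValueError("lambda1, lambda2 and b_thr must be non-negative")


def _omega_matrix(omega) -> np.ndarray:
    if isinstance(omega, WorkingPrecision):
        return omega.matrix
    return np.asarray(omega, dtype=float)


def group_norms(B: np.ndarray, bs: BlockSet) -> np.ndarray:
    """L2 norm of each intersection block of B (0 for an empty block)."""
    out = np.empty(bs.G)
    for g, blk in enumerate(bs.blocks):
        sub = B[np.ix_(blk.rows, blk.cols)]
        out[g] = np.sqrt(float((sub * sub).sum()))
    return out


def penalized_objective(X, Y, B, omega, pp: PenaltyParams, bs: BlockSet) -> float:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    B = np.asarray(B, dtype=float)
    Om = _omega_matrix(omega)
    if not (np.isfinite(X).all() and np.isfinite(Y).all() and np.isfinite(B).all()):
        raise ValueError("non-finite values in X, Y or B")
    n = X.shape[0]
    R = Y - X @ B
    loss = float(np.einsum("ik,il,kl->", R, R, Om)) / (2.0 * n)
    pen1 = pp.lambda1 * float(np.abs(B).sum())
    pen2 = pp.lambda2 * float(bs.weights @ group_norms(B, bs))
    return loss + pen1 + pen2


def partial_score(X, Y, B, omega, j: int, k: int) -> float:
    """S_jk = x_j' (Y - X B_(-jk)) Omega_.k with entry (j,k) of B zeroed."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Om = _omega_matrix(omega)
    Bm = np.array(B, dtype=float, copy=True)
    Bm[j, k] = 0.0
    return float(X[:, j] @ (Y - X @ Bm) @ Om[:, k])


def kkt_residual(X, Y, B, omega, pp: PenaltyParams, bs: BlockSet) -> float:
    """Max violation of the stationarity conditions of the objective at B.

    For non-overlapping blocks:

    * block with ||B_g|| = 0: the condition is
      || (|S0|/n - lambda1)_+ ||_2 <= lambda2 * w_g, where S0 is the score
      with the whole block zeroed (equivalently -n * smooth gradient there);
    * entry b != 0 in a nonzero block: |grad + lambda1*sgn(b) +
      lambda2*w_g*b/||B_g||| must vanish;
    * entry b == 0 in a nonzero block: |grad| <= lambda1.

    Returns the largest violation over all blocks and coordinates (0 when
    the KKT system holds exactly).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    B = np.asarray(B, dtype=float)
    Om = _omega_matrix(omega)
    n = X.shape[0]
    grad = (X.T @ (X @ B - Y) @ Om) / n  # smooth part gradient, p x q
    gn = group_norms(B, bs)
    worst = 0.0
    for g, blk in enumerate(bs.blocks):
        lam_g = pp.lambda2 * bs.weights[g]
        sub = np.ix_(blk.rows, blk.cols)
        if gn[g] == 0.0:
            r = np.maximum(np.abs(grad[sub]) - pp.lambda1, 0.0)
            worst = max(worst, float(np.sqrt((r * r).sum()) - lam_g))
        else:
            gsub = grad[sub] + pp.lambda2 * bs.weights[g] * B[sub] / gn[g]
            bsub = B[sub]
            nz = bsub != 0.0
            if nz.any():
                worst = max(
                    worst,
                    float(np.abs(gsub[nz] + pp.lambda1 * np.sign(bsub[nz])).max()),
                )
            if (~nz).any():
                worst = max(
                    worst, float((np.abs(gsub[~nz]) - pp.lambda1).max())
                )
    return max(worst, 0.0)
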