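"""Evaluation metrics: prediction MSE, coefficient MAEE, and support
precision/recall/F1.

Selection metrics are support-only: an entry counts as selected iff it is
not exactly 0.0 (thresholded estimates are exact zeros by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsReport",
    "mse",
    "maee",
    "selection_metrics",
    "evaluate_fit",
    "spearman_by_column",
]


@dataclass
class MetricsReport:
    mse: float | None = None
    maee: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None
    tn: int | None = None
    precision_undefined: bool = False

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _check_shapes(A, B, what):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"{what}: shape mismatch {A.shape} vs {B.shape}")
    return A, B


def mse(Y, Y_hat) -> float:
    """Mean squared prediction error over all n*q response entries."""
    Y, Y_hat = _check_shapes(Y, Y_hat, "mse")
    d = Y_hat - Y
    return float((d * d).sum() / d.size)


def maee(B_true, B_est) -> float:
    """Mean absolute estimation error over all p*q coefficients."""
    B_true, B_est = _check_shapes(B_true, B_est, "maee")
    return float(np.abs(B_est - B_true).sum() / B_true.size)


def selection_metrics(B_true, B_est) -> MetricsReport:
    """Support precision/recall/F1 with exact-zero support on both matrices.

    Degenerate denominators: an empty estimated support gives precision 0
    (flagged via ``precision_undefined``); precision + recall == 0 gives
    F1 = 0.
    """
    B_true, B_est = _check_shapes(B_true, B_est, "selection_metrics")
    t = B_true != 0.0
    e = B_est != 0.0
    tp = int((t & e).sum())
    fp = int((~t & e).sum())
    fn = int((t & ~e).sum())
    tn = int((~t & ~e).sum())
    undefined = (tp + fp) == 0
    prec = 0.0 if undefined else tp / (tp + fp)
    rec = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = 0.0 if (prec + rec) == 0 else 2.0 * prec * rec / (prec + rec)
    return MetricsReport(
        precision=prec, recall=rec, f1=f1,
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision_undefined=undefined,
    )


def evaluate_fit(B_true, B_est, Y_test=None, Y_pred=None) -> MetricsReport:
    """Combined report: MAEE + selection metrics, plus MSE when test
    responses and predictions are supplied."""
    rep = selection_metrics(B_true, B_est)
    rep.maee = maee(B_true, B_est)
    if Y_test is not None and Y_pred is not None:
        rep.mse = mse(Y_test, Y_pred)
    return rep


def spearman_by_column(Y, Y_hat) -> np.ndarray:
    """Spearman rank correlation per response column (utility for
    fraction-prediction style evaluations)."""
    from scipy.stats import spearmanr

    Y, Y_hat = _check_shapes(Y, Y_hat, "spearman")
    return np.array(
        [spearmanr(Y[:, k], Y_hat[:, k]).statistic for k in range(Y.shape[1])]
    )
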