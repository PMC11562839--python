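"""Working precision matrix for the weighted multivariate loss.

The loss tr((Y - XB)' (Y - XB) Omega) / (2n) weights residuals by a working
precision matrix Omega (an approximation of the inverse error covariance).
Omega is specified once, up front — it is never re-estimated inside the
solver.  Three sources are supported: the identity (which reduces the model
to the unweighted sparse-group fit), a block-diagonal estimate obtained by
inverting within-response-group sample covariances, and a user-supplied
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groups import GroupStructure

__all__ = [
    "WorkingPrecision",
    "identity_precision",
    "block_diagonal_precision",
    "load_user_precision",
]

_SYM_TOL = 1e-8
_PSD_TOL = 1e-8


@dataclass
class WorkingPrecision:
    """A validated q-by-q working precision matrix.

    Attributes
    ----------
    matrix
        Symmetric positive semidefinite values.
    source
        One of ``identity``, ``block_diagonal_estimated``, ``user_supplied``.
    names
        Optional response names aligned with the matrix.
    """

    matrix: np.ndarray
    source: str
    names: list[str] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("precision matrix must be square")
        if not np.isfinite(m).all():
            raise ValueError("precision matrix contains non-finite values")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > _SYM_TOL * scale:
            raise ValueError("precision matrix is not symmetric")
        m = 0.5 * (m + m.T)
        eig = np.linalg.eigvalsh(m)
        if eig.min() < -_PSD_TOL * max(eig.max(), 1.0):
            raise ValueError(
                f"precision matrix is not positive semidefinite "
                f"(min eigenvalue {eig.min():.3e})"
            )
        if (np.diag(m) <= 0).any():
            k = int(np.argmin(np.diag(m)))
            raise ValueError(f"diagonal entry {k} of the precision matrix is not > 0")
        self.matrix = m

    @property
    def q(self) -> int:
        return self.matrix.shape[0]

    @property
    def diag(self) -> np.ndarray:
        """Per-response diagonal weights omega_kk."""
        return np.diag(self.matrix)


def identity_precision(q: int) -> WorkingPrecision:
    """Identity weighting: responses treated as uncorrelated with unit
    variance, i.e. the plain (MSGLasso-style) sparse-group objective."""
    if q < 1:
        raise ValueError("q must be >= 1")
    return WorkingPrecision(np.eye(int(q)), source="identity")


def block_diagonal_precision(
    Yc: np.ndarray,
    yg: GroupStructure,
    ridge: float | None = None,
    ddof: int = 0,
) -> WorkingPrecision:
    """Invert within-group sample covariances of the centered responses.

    Each diagonal block of the result is ``inv(S_g + ridge_g * I)`` where
    S_g is the sample covariance (denominator ``n - ddof``, default n) of
    the responses in group g; off-diagonal blocks are exactly zero.

    Parameters
    ----------
    Yc
        Column-centered response matrix, n x q.
    yg
        Response grouping (must be non-overlapping for a well-defined
        block-diagonal structure).
    ridge
        Added to the diagonal of each within-group covariance before
        inversion.  ``None`` (default) uses ``1e-6 * trace(S_g) / |g|`` per
        block; ``0`` disables regularization and raises on singular blocks.
    """
    Yc = np.asarray(Yc, dtype=float)
    n, q = Yc.shape
    if np.abs(Yc.mean(axis=0)).max() > 1e-6 * max(1.0, np.abs(Yc).max()):
        raise ValueError("responses must be column-centered")
    if yg.overlapping:
        raise ValueError("block-diagonal precision requires non-overlapping response groups")
    if yg.n_features != q:
        raise ValueError("response grouping does not match the number of responses")
    omega = np.zeros((q, q))
    denom = n - ddof
    for gname, idx in yg.groups.items():
        Yg = Yc[:, idx]
        S = (Yg.T @ Yg) / denom
        m = idx.size
        r = 1e-6 * np.trace(S) / m if ridge is None else float(ridge)
        Sr = S + r * np.eye(m)
        eig = np.linalg.eigvalsh(Sr)
        if eig.min() <= 1e-12 * max(eig.max(), 1.0):
            raise np.linalg.LinAlgError(
                f"within-group covariance of response group {gname!r} is singular "
                f"(size {m}, n={n}); pass ridge > 0 or split the group"
            )
        block = np.linalg.inv(Sr)
        omega[np.ix_(idx, idx)] = 0.5 * (block + block.T)
    return WorkingPrecision(omega, source="block_diagonal_estimated", names=yg.labels)


def load_user_precision(path, response_names) -> WorkingPrecision:
    """Read a labelled square TSV/CSV and align it to the response order.

    The first row and column carry response names; rows/columns may be
    permuted relative to the response matrix and are realigned by name.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    names = [str(x) for x in response_names]
    missing = sorted(set(names) - set(map(str, df.index)))
    if missing or sorted(set(names) - set(map(str, df.columns))):
        missing = missing or sorted(set(names) - set(map(str, df.columns)))
        raise ValueError(f"{path}: precision matrix lacks responses: {', '.join(missing[:10])}")
    df = df.loc[names, names]
    return WorkingPrecision(df.to_numpy(dtype=float), source="user_supplied", names=names)


def write_precision(omega: WorkingPrecision, path, names=None) -> None:
    labels = names or omega.names or [f"y{i + 1}" for i in range(omega.q)]
    pd.DataFrame(omega.matrix, index=labels, columns=labels).to_csv(path, sep="\t")
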