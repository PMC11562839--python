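"""Independent reference implementations used only as test oracles.

These deliberately share no code path with the package: the penalized
objective is re-derived with naive loops, and the optimum is found by
accelerated proximal gradient (FISTA) with the exact proximal operator of
the elementwise-L1 + blockwise-L2 penalty (valid for non-overlapping
blocks), instead of coordinate descent.
"""

from __future__ import annotations

import numpy as np


def naive_objective(X, Y, B, Omega, lam1, lam2, blocks, weights):
    """Triple-loop recomputation of the penalized objective.

    ``blocks`` is a list of (rows, cols) index arrays; Omega a q x q array.
    """
    n, q = Y.shape
    R = np.empty_like(Y)
    for i in range(n):
        for k in range(q):
            acc = Y[i, k]
            for j in range(X.shape[1]):
                acc -= X[i, j] * B[j, k]
            R[i, k] = acc
    loss = 0.0
    for k in range(q):
        for l in range(q):
            s = 0.0
            for i in range(n):
                s += R[i, k] * R[i, l]
            loss += s * Omega[k, l]
    loss /= 2.0 * n
    pen1 = 0.0
    for j in range(B.shape[0]):
        for k in range(q):
            pen1 += abs(B[j, k])
    pen2 = 0.0
    for (rows, cols), w in zip(blocks, weights):
        s = 0.0
        for j in rows:
            for k in cols:
                s += B[j, k] ** 2
        pen2 += w * np.sqrt(s)
    return loss + lam1 * pen1 + lam2 * pen2


def _prox(B, t, lam1, lam2, blocks, weights):
    """Exact prox of t*(lam1*||.||_1 + lam2*sum w_g||B_g||_2) for a
    non-overlapping block partition: entrywise soft-threshold, then
    blockwise group soft-threshold."""
    Z = np.sign(B) * np.maximum(np.abs(B) - t * lam1, 0.0)
    out = np.zeros_like(Z)
    for (rows, cols), w in zip(blocks, weights):
        sub = Z[np.ix_(rows, cols)]
        nrm = np.sqrt((sub * sub).sum())
        if nrm > 0:
            out[np.ix_(rows, cols)] = sub * max(0.0, 1.0 - t * lam2 * w / nrm)
    return out


def fista_solve(X, Y, Omega, lam1, lam2, blocks, weights,
                max_iter=200_000, tol=1e-12):
    """Global minimizer of the penalized objective by accelerated proximal
    gradient with fixed step 1/L; returns (B, iterations)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Omega = np.asarray(Omega, float)
    n, p = X.shape
    q = Y.shape[1]
    XtX = X.T @ X
    XtY = X.T @ Y
    L = (np.linalg.eigvalsh(XtX).max() * np.linalg.eigvalsh(Omega).max()) / n
    t = 1.0 / L
    B = np.zeros((p, q))
    Z = B.copy()
    theta = 1.0
    for it in range(max_iter):
        grad = (XtX @ Z - XtY) @ Omega / n
        B_new = _prox(Z - t * grad, t, lam1, lam2, blocks, weights)
        theta_new = (1.0 + np.sqrt(1.0 + 4.0 * theta**2)) / 2.0
        Z = B_new + ((theta - 1.0) / theta_new) * (B_new - B)
        step = np.abs(B_new - B).max()
        B, theta = B_new, theta_new
        if step < tol:
            # fixed-point check on the non-accelerated map
            grad = (XtX @ B - XtY) @ Omega / n
            if np.abs(_prox(B - t * grad, t, lam1, lam2, blocks, weights) - B).max() < 10 * tol:
                return B, it + 1
    return B, max_iter


def random_sparse_group_instance(rng, n=40, P=2, Q=2, px=3, qy=2):
    """Small random problem: standardized X, response matrix, random PSD
    working precision, and a 2x2 non-overlapping block partition."""
    p, q = P * px, Q * qy
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    X /= np.sqrt((X * X).sum(axis=0))
    Y = rng.standard_normal((n, q)) + X @ (rng.standard_normal((p, q)) * (rng.random((p, q)) < 0.4))
    Y -= Y.mean(axis=0)
    A = rng.standard_normal((q, q))
    Omega = A @ A.T / q + 0.5 * np.eye(q)
    blocks = []
    for gi in range(P):
        for hj in range(Q):
            rows = np.arange(gi * px, (gi + 1) * px)
            cols = np.arange(hj * qy, (hj + 1) * qy)
            blocks.append((rows, cols))
    weights = np.array([np.sqrt(len(r) * len(c)) for r, c in blocks])
    return X, Y, Omega, blocks, weights
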