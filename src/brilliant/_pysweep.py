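"""Plain NumPy sweep, mirroring the compiled kernel.

Used as a readable reference for the Gauss-Seidel updates (tested to agree
with the numba kernel) and as the home of the Jacobi variant, in which every
score of a sweep is computed from the coefficients frozen at the sweep
start.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sweep_python"]


def _refresh_stats(B, bs, nnz, gnorm2):
    for g, blk in enumerate(bs.blocks):
        sub = B[np.ix_(blk.rows, blk.cols)]
        nz = sub != 0.0
        nnz[g] = int(nz.sum())
        gnorm2[g] = float((sub * sub).sum())


def _block_scores_zeroed(XtX, XtR, Om, B, blk, nnz_g):
    """Scores over a block with the whole block zeroed out."""
    S = XtR[blk.rows][:, :] @ Om[:, blk.cols]
    if nnz_g > 0:
        sub = B[np.ix_(blk.rows, blk.cols)]
        S = S + XtX[np.ix_(blk.rows, blk.rows)] @ sub @ Om[np.ix_(blk.cols, blk.cols)]
    return S


def _activate_block(XtX, XtR, Om, B, n, lam1, lam2, w, bs, nnz, gnorm2, g, blk, S, t_g):
    """One proximal-gradient step on an all-zero block that failed the
    zero-group screen: entrywise soft-threshold then group shrinkage."""
    Z = np.sign(S) * np.maximum(np.abs(S) / n - lam1, 0.0) * t_g
    znorm = np.sqrt(float((Z * Z).sum()))
    if znorm == 0.0:
        return 0.0
    factor = max(0.0, 1.0 - t_g * lam2 * w[g] / znorm)
    if factor == 0.0:
        return 0.0
    delta = 0.0
    for a, j in enumerate(blk.rows):
        for c, k in enumerate(blk.cols):
            v = factor * Z[a, c]
            if v != 0.0:
                B[j, k] = v
                XtR[:, k] -= XtX[:, j] * v
                delta = max(delta, abs(v))
                for m in bs.blocks_containing(j, k):
                    nnz[m] += 1
                    gnorm2[m] += v * v
    return delta


def sweep_python(XtX, XtR, Om, B, n, lam1, lam2, w, bs, nnz, gnorm2, active, clamp,
                 tstep=None, jacobi=False):
    p, q = B.shape
    delta = 0.0
    _refresh_stats(B, bs, nnz, gnorm2)

    if jacobi:
        B0 = B.copy()
        XtY = XtR + XtX @ B0
        XtR0 = XtR.copy()
        nnz0 = nnz.copy()
        gnorm0 = gnorm2.copy()

    # zero-group pass
    for g, blk in enumerate(bs.blocks):
        src_B = B0 if jacobi else B
        src_XtR = XtR0 if jacobi else XtR
        src_nnz = nnz0 if jacobi else nnz
        S = _block_scores_zeroed(XtX, src_XtR, Om, src_B, blk, src_nnz[g])
        t = np.abs(S) / n - lam1
        if clamp:
            t = np.maximum(t, 0.0)
        if np.sqrt(float((t * t).sum())) <= lam2 * w[g]:
            active[g] = False
            for j in blk.rows:
                for k in blk.cols:
                    v = B[j, k]
                    if v != 0.0:
                        B[j, k] = 0.0
                        XtR[:, k] += XtX[:, j] * v
                        delta = max(delta, abs(v))
                        for m in bs.blocks_containing(j, k):
                            nnz[m] -= 1
                            gnorm2[m] -= v * v
        else:
            active[g] = True
            if (
                not jacobi
                and nnz[g] == 0
                and tstep is not None
                and tstep[g] > 0.0
            ):
                d = _activate_block(
                    XtX, XtR, Om, B, n, lam1, lam2, w, bs, nnz, gnorm2,
                    g, blk, S, tstep[g],
                )
                delta = max(delta, d)

    # coordinate pass
    for j in range(p):
        for k in range(q):
            membs = bs.blocks_containing(j, k)
            if not membs or not any(active[m] for m in membs):
                continue
            if jacobi:
                bold_s = B0[j, k]
                s = float(XtR0[j] @ Om[:, k]) + bold_s * XtX[j, j] * Om[k, k]
                nnz_src, gn_src = nnz0, gnorm0
            else:
                bold_s = B[j, k]
                s = float(XtR[j] @ Om[:, k]) + bold_s * XtX[j, j] * Om[k, k]
                nnz_src, gn_src = nnz, gnorm2
            thr = n * lam1
            den = XtX[j, j] * Om[k, k]
            for m in membs:
                rest = nnz_src[m] - (1 if bold_s != 0.0 else 0)
                if rest == 0:
                    thr += n * lam2 * w[m]
                else:
                    den += n * lam2 * w[m] / max(np.sqrt(gn_src[m]), 1e-12)
            a = abs(s) - thr
            bnew = 0.0 if a <= 0.0 else (a / den if s > 0 else -a / den)
            bold = B[j, k]
            if bnew != bold:
                d = bnew - bold
                if not jacobi:
                    XtR[:, k] -= XtX[:, j] * d
                    for m in membs:
                        gnorm2[m] += bnew * bnew - bold * bold
                        nnz[m] += int(bnew != 0.0) - int(bold != 0.0)
                B[j, k] = bnew
            if jacobi:
                delta = max(delta, abs(bnew - bold_s))
            else:
                delta = max(delta, abs(bnew - bold))

    if jacobi:
        XtR[:, :] = XtY - XtX @ B
        _refresh_stats(B, bs, nnz, gnorm2)
    return delta
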