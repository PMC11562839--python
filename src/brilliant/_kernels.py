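"""Numba inner loop for the mixed coordinate descent.

One call performs one full sweep: a zero-group pass over all blocks (the
exact block-KKT screen, with a proximal activation step for blocks that
fail the screen while sitting entirely at zero — single-coordinate moves
cannot escape that point because the group norm is not separable at 0),
followed by a Gauss-Seidel coordinate pass in row-major (j, k) order.
State is carried in XtR = X'(Y - XB), which is updated incrementally, so a
coordinate visit costs O(p + q) instead of O(n q).  Group norms and exact
nonzero counts per block are refreshed at the start of every sweep to kill
floating-point drift.
"""

import numpy as np
from numba import njit

__all__ = ["sweep_gauss_seidel"]


@njit(cache=True)
def sweep_gauss_seidel(
    XtX,
    XtR,
    Omega,
    B,
    n,
    lam1,
    lam2,
    w,
    br_ptr,
    br_idx,
    bc_ptr,
    bc_idx,
    memb_ptr,
    memb_idx,
    nnz,
    gnorm2,
    active,
    clamp,
    tstep,
):
    p, q = B.shape
    G = w.shape[0]
    delta = 0.0
    max_be = 0
    for g in range(G):
        be = (br_ptr[g + 1] - br_ptr[g]) * (bc_ptr[g + 1] - bc_ptr[g])
        if be > max_be:
            max_be = be
    scratch = np.empty(max_be)

    # refresh per-block stats from the current B (exact zero counts)
    for g in range(G):
        s2 = 0.0
        cnt = 0
        for a in range(br_ptr[g], br_ptr[g + 1]):
            j = br_idx[a]
            for c in range(bc_ptr[g], bc_ptr[g + 1]):
                k = bc_idx[c]
                v = B[j, k]
                if v != 0.0:
                    s2 += v * v
                    cnt += 1
        gnorm2[g] = s2
        nnz[g] = cnt

    # ---- zero-group pass: exact KKT screen per block -------------------
    for g in range(G):
        lam_g = lam2 * w[g]
        stat2 = 0.0
        pos = 0
        for a in range(br_ptr[g], br_ptr[g + 1]):
            j = br_idx[a]
            for c in range(bc_ptr[g], bc_ptr[g + 1]):
                k = bc_idx[c]
                s = 0.0
                for kk in range(q):
                    s += XtR[j, kk] * Omega[kk, k]
                if nnz[g] > 0:
                    # score with the whole block zeroed: add back the
                    # block's own contribution to the residual
                    for a2 in range(br_ptr[g], br_ptr[g + 1]):
                        j2 = br_idx[a2]
                        for c2 in range(bc_ptr[g], bc_ptr[g + 1]):
                            k2 = bc_idx[c2]
                            v = B[j2, k2]
                            if v != 0.0:
                                s += XtX[j, j2] * v * Omega[k2, k]
                scratch[pos] = s
                pos += 1
                t = abs(s) / n - lam1
                if clamp and t < 0.0:
                    t = 0.0
                stat2 += t * t
        if np.sqrt(stat2) <= lam_g:
            active[g] = False
            for a in range(br_ptr[g], br_ptr[g + 1]):
                j = br_idx[a]
                for c in range(bc_ptr[g], bc_ptr[g + 1]):
                    k = bc_idx[c]
                    v = B[j, k]
                    if v != 0.0:
                        B[j, k] = 0.0
                        for jj in range(p):
                            XtR[jj, k] += XtX[jj, j] * v
                        if abs(v) > delta:
                            delta = abs(v)
                        base = j * q + k
                        for mp in range(memb_ptr[base], memb_ptr[base + 1]):
                            m = memb_idx[mp]
                            nnz[m] -= 1
                            gnorm2[m] -= v * v
        else:
            active[g] = True
            if nnz[g] == 0 and tstep[g] > 0.0:
                # proximal activation: one block prox-gradient step from 0
                # (entrywise soft-threshold, then group shrinkage); strictly
                # decreases the objective and makes the block nonzero
                t_g = tstep[g]
                zn2 = 0.0
                for i in range(pos):
                    z = (abs(scratch[i]) / n - lam1) * t_g
                    if z > 0.0:
                        zn2 += z * z
                znorm = np.sqrt(zn2)
                if znorm > 0.0:
                    factor = 1.0 - t_g * lam2 * w[g] / znorm
                    if factor > 0.0:
                        pos = 0
                        for a in range(br_ptr[g], br_ptr[g + 1]):
                            j = br_idx[a]
                            for c in range(bc_ptr[g], bc_ptr[g + 1]):
                                k = bc_idx[c]
                                s = scratch[pos]
                                pos += 1
                                z = (abs(s) / n - lam1) * t_g
                                if z > 0.0:
                                    v = factor * z
                                    if s < 0.0:
                                        v = -v
                                    B[j, k] = v
                                    for jj in range(p):
                                        XtR[jj, k] -= XtX[jj, j] * v
                                    if abs(v) > delta:
                                        delta = abs(v)
                                    base = j * q + k
                                    for mp in range(memb_ptr[base], memb_ptr[base + 1]):
                                        m = memb_idx[mp]
                                        nnz[m] += 1
                                        gnorm2[m] += v * v

    # ---- coordinate pass, row-major over (j, k) -------------------------
    for j in range(p):
        for k in range(q):
            base = j * q + k
            lo = memb_ptr[base]
            hi = memb_ptr[base + 1]
            if lo == hi:
                continue
            anyact = False
            for a in range(lo, hi):
                if active[memb_idx[a]]:
                    anyact = True
                    break
            if not anyact:
                continue
            bold = B[j, k]
            s = 0.0
            for kk in range(q):
                s += XtR[j, kk] * Omega[kk, k]
            s += bold * XtX[j, j] * Omega[k, k]
            thr = n * lam1
            den = XtX[j, j] * Omega[k, k]
            for a in range(lo, hi):
                m = memb_idx[a]
                rest = nnz[m]
                if bold != 0.0:
                    rest -= 1
                if rest == 0:
                    thr += n * lam2 * w[m]
                else:
                    gnm = np.sqrt(gnorm2[m])
                    if gnm < 1e-12:
                        gnm = 1e-12
                    den += n * lam2 * w[m] / gnm
            av = abs(s) - thr
            if av > 0.0:
                bnew = av / den
                if s < 0.0:
                    bnew = -bnew
            else:
                bnew = 0.0
            if bnew != bold:
                d = bnew - bold
                for jj in range(p):
                    XtR[jj, k] -= XtX[jj, j] * d
                for a in range(lo, hi):
                    m = memb_idx[a]
                    gnorm2[m] += bnew * bnew - bold * bold
                    if bold != 0.0:
                        nnz[m] -= 1
                    if bnew != 0.0:
                        nnz[m] += 1
                B[j, k] = bnew
                if abs(d) > delta:
                    delta = abs(d)
    return delta
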