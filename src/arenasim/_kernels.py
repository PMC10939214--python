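"""Numba kernels for the monthly integration step.

Everything here operates on plain arrays; the public API and all
bookkeeping live in :mod:`arenasim.ecosim`.  The kernel advances one
month: fast (plankton-like) groups are relaxed to their moving
equilibrium, slow groups take exponential predictor-corrector sub-steps
(or explicit AB2 when requested).
"""

from __future__ import annotations

import numba as nb
import numpy as np

RELAX_TOL = 1e-9
RELAX_MAX_ITER = 200


@nb.njit(cache=True)
def _rates(B, prey, pred, a, v, g_eff, imp_qb, M0, F_t, alpha, r, h,
           is_prod, is_ode, Ql, Qin, Qout, G, lam):
    n = B.size
    for i in range(n):
        Qin[i] = 0.0
        Qout[i] = 0.0
    for l in range(prey.size):
        bj = B[pred[l]]
        q = a[l] * v[l] * B[prey[l]] * bj / (2.0 * v[l] + a[l] * bj)
        Ql[l] = q
        Qin[pred[l]] += q
        Qout[prey[l]] += q
    for i in range(n):
        if is_ode[i]:
            if is_prod[i]:
                G[i] = alpha * r[i] * B[i] / (1.0 + h[i] * B[i])
            else:
                G[i] = g_eff[i] * (Qin[i] + imp_qb[i] * B[i])
        else:
            G[i] = 0.0
        bs = B[i] if B[i] > 0.0 else 1.0
        lam[i] = Qout[i] / bs + M0[i] + F_t[i]


@nb.njit(cache=True)
def _relax_fast(B, fast_idx, prey, pred, a, v, g_eff, imp_qb, M0, F_t,
                alpha, r, h, is_prod, is_ode, Ql, Qin, Qout, G, lam):
    if fast_idx.size == 0:
        return
    for _ in range(RELAX_MAX_ITER):
        _rates(B, prey, pred, a, v, g_eff, imp_qb, M0, F_t, alpha, r, h,
               is_prod, is_ode, Ql, Qin, Qout, G, lam)
        delta = 0.0
        for k in fast_idx:
            lam_k = lam[k] if lam[k] > 1e-12 else 1e-12
            tgt = G[k] / lam_k
            bk = B[k] if B[k] > 1e-30 else 1e-30
            d = abs(tgt - B[k]) / bk
            if d > delta:
                delta = d
            B[k] = tgt
        if delta < RELAX_TOL:
            break


@nb.njit(cache=True)
def advance_month(B, prey, pred, a, v, g_eff, imp_qb, M0, F_t, alpha, r, h,
                  is_prod, is_ode, is_slow, fast_idx, steps, dt, floor_B,
                  exponential, prev_deriv, have_prev,
                  Ql, Qin, Qout):
    """Advance all non-stanza, non-forced groups one month in place.

    Returns (floor_count, all_finite, have_prev).  On exit Ql/Qin/Qout hold
    the end-of-month flow rates (fast groups re-relaxed), for the stanza
    update and the mortality ledger.
    """
    n = B.size
    G0 = np.empty(n)
    lam0 = np.empty(n)
    G1 = np.empty(n)
    lam1 = np.empty(n)
    Bp = np.empty(n)
    nfloor = 0
    finite = True

    for _ in range(steps):
        if exponential:
            _relax_fast(B, fast_idx, prey, pred, a, v, g_eff, imp_qb, M0,
                        F_t, alpha, r, h, is_prod, is_ode, Ql, Qin, Qout, G0, lam0)
            _rates(B, prey, pred, a, v, g_eff, imp_qb, M0, F_t, alpha, r, h,
                   is_prod, is_ode, Ql, Qin, Qout, G0, lam0)
            # predictor for slow groups
            for i in range(n):
                if is_slow[i]:
                    lam_s = lam0[i] if lam0[i] > 1e-12 else 1e-12
                    beq = G0[i] / lam_s
                    Bp[i] = beq + (B[i] - beq) * np.exp(-lam_s * dt)
                else:
                    Bp[i] = B[i]
            _relax_fast(Bp, fast_idx, prey, pred, a, v, g_eff, imp_qb, M0,
                        F_t, alpha, r, h, is_prod, is_ode, Ql, Qin, Qout, G1, lam1)
            _rates(Bp, prey, pred, a, v, g_eff, imp_qb, M0, F_t, alpha, r, h,
                   is_prod, is_ode, Ql, Qin, Qout, G1, lam1)
            # corrector with averaged gains/losses
            for i in range(n):
                if is_slow[i]:
                    gm = 0.5 * (G0[i] + G1[i])
                    lm = 0.5 * (lam0[i] + lam1[i])
                    if lm < 1e-12:
                        lm = 1e-12
                    beq = gm / lm
                    B[i] = beq + (B[i] - beq) * np.exp(-lm * dt)
        else:
            _rates(B, prey, pred, a, v, g_eff, imp_qb, M0, F_t, alpha, r, h,
                   is_prod, is_ode, Ql, Qin, Qout, G0, lam0)
            for i in range(n):
                d = G0[i] - lam0[i] * B[i] if is_ode[i] else 0.0
                if have_prev:
                    B[i] = B[i] + dt * (1.5 * d - 0.5 * prev_deriv[i])
                else:
                    B[i] = B[i] + dt * d
                prev_deriv[i] = d
            have_prev = True

        for i in range(n):
            if is_ode[i] and B[i] < floor_B[i]:
                B[i] = floor_B[i]
                nfloor += 1
            if not np.isfinite(B[i]):
                finite = False
        if not finite:
            return nfloor, finite, have_prev

    # leave flows consistent with the end-of-month state
    if exponential:
        _relax_fast(B, fast_idx, prey, pred, a, v, g_eff, imp_qb, M0, F_t,
                    alpha, r, h, is_prod, is_ode, Ql, Qin, Qout, G0, lam0)
    _rates(B, prey, pred, a, v, g_eff, imp_qb, M0, F_t, alpha, r, h,
           is_prod, is_ode, Ql, Qin, Qout, G0, lam0)
    return nfloor, finite, have_prev
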