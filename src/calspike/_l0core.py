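"""Numba kernel for the constrained L0 functional dynamic program.

The optimal cost-to-go at each timestep is a continuous piecewise-quadratic
function of the calcium value, stored as parallel arrays: piece ``i`` is
``a*c^2 + b*c + d`` on ``[L[i], L[i+1])``; ``L[0]`` is the ``-inf``
sentinel ``_NEG``.  All pieces of a cost function carry at least one
``c^2/2`` data term, so ``a > 0`` and every piece has a finite vertex.

The recursion per timestep:

* ``M`` = running minimum of the previous cost (min over ``c' <= x``);
* spike branch   = ``M(c/gamma) + lam``;
* no-spike branch = (truncated) previous cost at ``c/gamma``;
* new cost = pointwise min of the branches plus ``(y_t - c)^2 / 2``.

Truncating the previous cost at ``M + lam`` is exact (where the cost
exceeds it, a spike-restart is at least as good) and bounds the stored
piece count.  Ties in the branch minimum resolve to the spike branch so
that truncation-induced tie regions trace back correctly; jumps below the
caller's tolerance are discarded afterwards.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -1e300  # -inf sentinel for interval lower bounds


@njit(cache=True)
def _min_accum(L, A, B, D, n, oL, oA, oB, oD):
    """Running minimum M(x) = min_{c <= x} f(c).  Returns piece count."""
    m = np.inf
    k = 0
    for i in range(n):
        lo = L[i]
        hi = L[i + 1] if i + 1 < n else np.inf
        a = A[i]
        b = B[i]
        d = D[i]
        v = -b / (2.0 * a)
        dec_hi = hi if hi < v else v
        if dec_hi > lo:
            q_lo = (a * lo + b) * lo + d if lo > _NEG else np.inf
            if q_lo > m:
                disc = b * b - 4.0 * a * (d - m)
                x = (-b - np.sqrt(disc)) / (2.0 * a) if disc > 0.0 else np.inf
                if x < dec_hi:
                    # constant m until the crossing, then follow the quadratic
                    if k == 0 or not (oA[k - 1] == 0.0 and oB[k - 1] == 0.0 and oD[k - 1] == m):
                        oL[k] = lo
                        oA[k] = 0.0
                        oB[k] = 0.0
                        oD[k] = m
                        k += 1
                    oL[k] = x
                    oA[k] = a
                    oB[k] = b
                    oD[k] = d
                    k += 1
                    m = (a * dec_hi + b) * dec_hi + d
                else:
                    if k == 0 or not (oA[k - 1] == 0.0 and oB[k - 1] == 0.0 and oD[k - 1] == m):
                        oL[k] = lo
                        oA[k] = 0.0
                        oB[k] = 0.0
                        oD[k] = m
                        k += 1
                    end_val = (a * dec_hi + b) * dec_hi + d
                    if end_val < m:
                        m = end_val
            else:
                oL[k] = lo
                oA[k] = a
                oB[k] = b
                oD[k] = d
                k += 1
                m = (a * dec_hi + b) * dec_hi + d
        if hi > v or dec_hi <= lo:
            inc_lo = lo if v < lo else v
            if hi > inc_lo:
                q_inc = (a * inc_lo + b) * inc_lo + d
                if q_inc < m:
                    m = q_inc
                if k > 0 and oA[k - 1] == 0.0 and oB[k - 1] == 0.0 and oD[k - 1] == m:
                    pass  # merge with the previous identical constant
                else:
                    oL[k] = inc_lo
                    oA[k] = 0.0
                    oB[k] = 0.0
                    oD[k] = m
                    k += 1
    return k


@njit(cache=True)
def _pmin(Lf, Af, Bf, Df, Ff, nf, Lg, Ag, Bg, Dg, Fg, ng, oL, oA, oB, oD, oF):
    """Pointwise min with flag propagation; ties go to g.  Returns count."""
    k = 0
    i = 0
    j = 0
    lo = _NEG
    while True:
        hi_f = Lf[i + 1] if i + 1 < nf else np.inf
        hi_g = Lg[j + 1] if j + 1 < ng else np.inf
        hi = hi_f if hi_f < hi_g else hi_g
        da = Af[i] - Ag[j]
        db = Bf[i] - Bg[j]
        dd = Df[i] - Dg[j]
        r1 = np.inf
        r2 = np.inf
        if da != 0.0:
            disc = db * db - 4.0 * da * dd
            if disc > 0.0:
                s = np.sqrt(disc)
                ra = (-db - s) / (2.0 * da)
                rb = (-db + s) / (2.0 * da)
                if ra < rb:
                    r1 = ra
                    r2 = rb
                else:
                    r1 = rb
                    r2 = ra
        elif db != 0.0:
            r1 = -dd / db
        pa = lo
        pb = np.inf  # candidate subinterval starts beyond lo
        pc = np.inf
        npts = 1
        if lo < r1 < hi:
            pb = r1
            npts = 2
        if lo < r2 < hi and r2 != r1:
            if npts == 2:
                pc = r2
                npts = 3
            else:
                pb = r2
                npts = 2
        for idx in range(npts):
            p_lo = pa if idx == 0 else (pb if idx == 1 else pc)
            p_hi = hi if idx == npts - 1 else (pb if idx == 0 else pc)
            if p_lo <= _NEG:
                tp = p_hi - 1.0 if p_hi < np.inf else 0.0
            elif p_hi == np.inf:
                tp = p_lo + 1.0
            else:
                tp = 0.5 * (p_lo + p_hi)
            if (da * tp + db) * tp + dd < 0.0:
                na, nb, nd, nfl = Af[i], Bf[i], Df[i], Ff[i]
            else:
                na, nb, nd, nfl = Ag[j], Bg[j], Dg[j], Fg[j]
            if k > 0 and p_lo <= oL[k - 1]:
                oA[k - 1] = na
                oB[k - 1] = nb
                oD[k - 1] = nd
                oF[k - 1] = nfl
            elif k > 0 and oA[k - 1] == na and oB[k - 1] == nb and oD[k - 1] == nd and oF[k - 1] == nfl:
                pass
            else:
                oL[k] = p_lo
                oA[k] = na
                oB[k] = nb
                oD[k] = nd
                oF[k] = nfl
                k += 1
        if hi == np.inf:
            break
        lo = hi
        if hi_f == hi:
            i += 1
        if hi_g == hi:
            j += 1
    return k


@njit(cache=True)
def _argmin_leq(L, A, B, D, n, x_max):
    """Location/value of the minimum over (-inf, x_max]."""
    best_x = 0.0
    best_v = np.inf
    for i in range(n):
        lo = L[i]
        if lo >= x_max:
            break
        hi = L[i + 1] if i + 1 < n else np.inf
        if hi > x_max:
            hi = x_max
        a = A[i]
        b = B[i]
        d = D[i]
        if a > 0.0:
            v = -b / (2.0 * a)
            cand = lo if v < lo else (hi if v > hi else v)
        elif b > 0.0:
            cand = lo
        elif b < 0.0:
            cand = hi
        else:
            cand = hi if lo <= _NEG else lo
        if cand <= _NEG or cand == np.inf:
            continue
        val = (a * cand + b) * cand + d
        if val < best_v:
            best_v = val
            best_x = cand
    return best_x, best_v


@njit(cache=True)
def solve_dp(y, gamma, lam):
    """Full DP + traceback.  Returns (c_path, spike_flags, objective)."""
    T = y.size
    MAXP = 4096
    # current cost
    cL = np.empty(MAXP)
    cA = np.empty(MAXP)
    cB = np.empty(MAXP)
    cD = np.empty(MAXP)
    cF = np.zeros(MAXP, dtype=np.int8)
    cn = 1
    cL[0] = _NEG
    cA[0] = 0.5
    cB[0] = -y[0]
    cD[0] = 0.5 * y[0] * y[0]

    # scratch
    mL = np.empty(MAXP)
    mA = np.empty(MAXP)
    mB = np.empty(MAXP)
    mD = np.empty(MAXP)
    mF = np.zeros(MAXP, dtype=np.int8)
    tL = np.empty(MAXP)
    tA = np.empty(MAXP)
    tB = np.empty(MAXP)
    tD = np.empty(MAXP)
    tF = np.zeros(MAXP, dtype=np.int8)
    gL = np.empty(MAXP)
    gA = np.empty(MAXP)
    gB = np.empty(MAXP)
    gD = np.empty(MAXP)
    gF = np.ones(MAXP, dtype=np.int8)
    uL = np.empty(MAXP)
    uA = np.empty(MAXP)
    uB = np.empty(MAXP)
    uD = np.empty(MAXP)
    uF = np.zeros(MAXP, dtype=np.int8)

    # storage for traceback
    cap = 32 * T + MAXP
    sL = np.empty(cap)
    sA = np.empty(cap)
    sB = np.empty(cap)
    sD = np.empty(cap)
    sF = np.zeros(cap, dtype=np.int8)
    offs = np.zeros(T + 1, dtype=np.int64)
    pos = 0
    sL[0] = cL[0]
    sA[0] = cA[0]
    sB[0] = cB[0]
    sD[0] = cD[0]
    sF[0] = 0
    pos = 1
    offs[1] = 1

    g2 = gamma * gamma
    for t in range(1, T):
        # M = running min of current cost
        mn = _min_accum(cL, cA, cB, cD, cn, mL, mA, mB, mD)
        # truncate cost at M + lam (exact pruning); ties resolve to M + lam
        for i in range(mn):
            tL[i] = mL[i]
            tA[i] = mA[i]
            tB[i] = mB[i]
            tD[i] = mD[i] + lam
        tn = _pmin(cL, cA, cB, cD, cF, cn, tL, tA, tB, tD, tF, mn, uL, uA, uB, uD, uF)
        # no-spike branch: truncated cost with argument c/gamma
        for i in range(tn):
            gLv = uL[i]
            tL[i] = gLv * gamma if gLv > _NEG else _NEG
            tA[i] = uA[i] / g2
            tB[i] = uB[i] / gamma
            tD[i] = uD[i]
            tF[i] = 0
        # spike branch: M(c/gamma) + lam
        for i in range(mn):
            mLv = mL[i]
            gL[i] = mLv * gamma if mLv > _NEG else _NEG
            gA[i] = mA[i] / g2
            gB[i] = mB[i] / gamma
            gD[i] = mD[i] + lam
        cn = _pmin(tL, tA, tB, tD, tF, tn, gL, gA, gB, gD, gF, mn, cL, cA, cB, cD, cF)
        yt = y[t]
        dq = 0.5 * yt * yt
        for i in range(cn):
            cA[i] += 0.5
            cB[i] -= yt
            cD[i] += dq
        # store
        if pos + cn > cap:
            new_cap = 2 * cap + cn
            nsL = np.empty(new_cap)
            nsA = np.empty(new_cap)
            nsB = np.empty(new_cap)
            nsD = np.empty(new_cap)
            nsF = np.zeros(new_cap, dtype=np.int8)
            nsL[:pos] = sL[:pos]
            nsA[:pos] = sA[:pos]
            nsB[:pos] = sB[:pos]
            nsD[:pos] = sD[:pos]
            nsF[:pos] = sF[:pos]
            sL, sA, sB, sD, sF = nsL, nsA, nsB, nsD, nsF
            cap = new_cap
        for i in range(cn):
            sL[pos + i] = cL[i]
            sA[pos + i] = cA[i]
            sB[pos + i] = cB[i]
            sD[pos + i] = cD[i]
            sF[pos + i] = cF[i]
        pos += cn
        offs[t + 1] = pos

    # traceback
    c_path = np.empty(T)
    spike = np.zeros(T, dtype=np.int8)
    o0 = offs[T - 1]
    o1 = offs[T]
    c, obj = _argmin_leq(sL[o0:o1], sA[o0:o1], sB[o0:o1], sD[o0:o1], o1 - o0, np.inf)
    c_path[T - 1] = c
    for t in range(T - 1, 0, -1):
        o0 = offs[t]
        o1 = offs[t + 1]
        # find piece containing c
        i = o0
        while i + 1 < o1 and sL[i + 1] <= c:
            i += 1
        if sF[i] == 1:
            spike[t] = 1
            p0 = offs[t - 1]
            p1 = offs[t]
            c, _v = _argmin_leq(
                sL[p0:p1], sA[p0:p1], sB[p0:p1], sD[p0:p1], p1 - p0, c / gamma
            )
        else:
            c = c / gamma
        c_path[t - 1] = c
    return c_path, spike, obj
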