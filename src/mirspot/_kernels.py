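"""Numba kernels for intermolecular duplex energy minimisation.

Both kernels optimise over *admissible* duplex structures: antiparallel,
non-crossing base pairs (Watson-Crick or G:U), every maximal helix of length
>= 2 (no lonely pairs), no G:U among the first eight pairs and fewer than
five G:U pairs in total.  Energies follow the bundled nearest-neighbor model:

    E = init + sum(stacks) + sum(loop penalties) + terminal AU/GU penalties
        at both ends of every maximal helix.

The pair-count state ``c`` tracks the G:U bookkeeping: c in [0, 6] means
ordinal pair 1..7 placed so far (G:U still forbidden), c in [7, 11] means
>= 8 pairs placed with (c - 7) G:U pairs used.
"""
from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e30
BIG = 1e29

# pair type codes, keyed (guide base code, target base code); -1 = not pairable
# base codes: A=0, C=1, G=2, U=3; pair types: AU=0, UA=1, GC=2, CG=3, GU=4, UG=5
PTYPE = -np.ones((4, 4), dtype=np.int8)
PTYPE[0, 3] = 0
PTYPE[3, 0] = 1
PTYPE[2, 1] = 2
PTYPE[1, 2] = 3
PTYPE[2, 3] = 4
PTYPE[3, 2] = 5

#: 1 where the pair type carries the terminal AU/GU penalty
TERM_MASK = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 1.0])


def _build_step(n_flags: int) -> np.ndarray:
    """State transition c -> c' when adding one pair (second axis: is G:U)."""
    step = -np.ones((12 * n_flags, 2), dtype=np.int8)
    for f in range(n_flags):
        off = 12 * f
        for c in range(12):
            # non-G:U pair
            if c < 6:
                step[off + c, 0] = off + c + 1
            elif c == 6:
                step[off + c, 0] = off + 7
            else:
                step[off + c, 0] = off + c
            # G:U pair: forbidden among the first eight pairs, at most 4 total
            if 7 <= c < 11:
                step[off + c, 1] = off + c + 1
    return step


STEP12 = _build_step(1)
STEP24 = _build_step(2)


@njit(cache=True)
def exact_anchored_dp(mi, ut, a0, span, stack, bulge, interior, init_e, term6,
                      max_loop, require_seed, first_i_max):
    """Minimum-energy admissible duplex anchored at UTR position ``a0`` (0-based).

    The 5'-most paired microRNA base pairs with ``ut[a0]``; 3'-side pairing is
    searched in the window [a0 - span, a0].  ``require_seed`` forces the
    structure to begin with the stacked Watson-Crick helix over microRNA
    positions 1..7.  ``first_i_max`` (if >= 0) restricts the 5'-most paired
    microRNA index (0-based) to <= first_i_max.

    Returns (found, energy, pairs) with pairs as an (n, 2) array of 0-based
    (mi index, utr index), mi ascending.
    """
    m = mi.shape[0]
    jlo = a0 - span
    if jlo < 0:
        jlo = 0
    w = a0 - jlo + 1
    E = np.full((m, w, 2, 12), INF)
    NP = np.zeros((m, w, 2, 12), dtype=np.int16)
    Bi = np.full((m, w, 2, 12), -2, dtype=np.int16)
    Bj = np.full((m, w, 2, 12), -2, dtype=np.int16)
    Bs = np.full((m, w, 2, 12), -2, dtype=np.int16)
    Bc = np.full((m, w, 2, 12), -2, dtype=np.int16)

    if require_seed:
        if a0 - 6 < jlo or m < 7:
            return False, 0.0, np.empty((0, 2), dtype=np.int32)
        e = init_e
        ok = True
        for k in range(7):
            pt = PTYPE[mi[k], ut[a0 - k]]
            if pt < 0 or pt >= 4:
                ok = False
                break
        if not ok:
            return False, 0.0, np.empty((0, 2), dtype=np.int32)
        pt0 = PTYPE[mi[0], ut[a0]]
        e += term6[pt0]
        for k in range(6):
            e += stack[PTYPE[mi[k], ut[a0 - k]], PTYPE[mi[k + 1], ut[a0 - k - 1]]]
        E[6, w - 7, 1, 6] = e
        NP[6, w - 7, 1, 6] = 7
        Bi[6, w - 7, 1, 6] = -1
    else:
        imax = m - 1
        if first_i_max >= 0 and first_i_max < imax:
            imax = first_i_max
        for i0 in range(imax + 1):
            pt = PTYPE[mi[i0], ut[a0]]
            if pt >= 0 and pt < 4:  # first pair: ordinal 1, G:U forbidden
                E[i0, w - 1, 0, 0] = init_e + term6[pt]
                NP[i0, w - 1, 0, 0] = 1
                Bi[i0, w - 1, 0, 0] = -1

    for j in range(w - 1, 0, -1):
        ug = ut[jlo + j]
        for i in range(m - 1):
            pt1 = PTYPE[mi[i], ug]
            if pt1 < 0:
                continue
            te1 = term6[pt1]
            for s in range(2):
                for c in range(12):
                    e = E[i, j, s, c]
                    if e >= BIG:
                        continue
                    npair = NP[i, j, s, c]
                    # stacked extension
                    i2 = i + 1
                    j2 = j - 1
                    pt2 = PTYPE[mi[i2], ut[jlo + j2]]
                    if pt2 >= 0:
                        gu2 = 1 if pt2 >= 4 else 0
                        c2 = STEP12[c, gu2]
                        if c2 >= 0:
                            cand = e + stack[pt1, pt2]
                            cur = E[i2, j2, 1, c2]
                            if cand < cur or (cand == cur and npair + 1 < NP[i2, j2, 1, c2]):
                                E[i2, j2, 1, c2] = cand
                                NP[i2, j2, 1, c2] = npair + 1
                                Bi[i2, j2, 1, c2] = i
                                Bj[i2, j2, 1, c2] = j
                                Bs[i2, j2, 1, c2] = s
                                Bc[i2, j2, 1, c2] = c
                    # loop opening (only from a completed helix)
                    if s == 1:
                        amax = m - 2 - i
                        if amax > max_loop:
                            amax = max_loop
                        for a in range(amax + 1):
                            i2 = i + 1 + a
                            bmax = j - 1
                            if bmax > max_loop:
                                bmax = max_loop
                            for b in range(bmax + 1):
                                if a == 0 and b == 0:
                                    continue
                                j2 = j - 1 - b
                                pt2 = PTYPE[mi[i2], ut[jlo + j2]]
                                if pt2 < 0:
                                    continue
                                gu2 = 1 if pt2 >= 4 else 0
                                c2 = STEP12[c, gu2]
                                if c2 < 0:
                                    continue
                                if a == 0:
                                    pen = bulge[b]
                                elif b == 0:
                                    pen = bulge[a]
                                else:
                                    pen = interior[a + b]
                                cand = e + te1 + pen + term6[pt2]
                                cur = E[i2, j2, 0, c2]
                                if cand < cur or (cand == cur and npair + 1 < NP[i2, j2, 0, c2]):
                                    E[i2, j2, 0, c2] = cand
                                    NP[i2, j2, 0, c2] = npair + 1
                                    Bi[i2, j2, 0, c2] = i
                                    Bj[i2, j2, 0, c2] = j
                                    Bs[i2, j2, 0, c2] = s
                                    Bc[i2, j2, 0, c2] = c

    best = INF
    bnp = np.int16(0)
    bi = -1
    bj = -1
    bc = -1
    for i in range(m):
        for j in range(w):
            pt = PTYPE[mi[i], ut[jlo + j]]
            if pt < 0:
                continue
            te = term6[pt]
            for c in range(12):
                e = E[i, j, 1, c]
                if e >= BIG:
                    continue
                tot = e + te
                if tot < best or (tot == best and NP[i, j, 1, c] < bnp):
                    best = tot
                    bnp = NP[i, j, 1, c]
                    bi = i
                    bj = j
                    bc = c
    if bi < 0:
        return False, 0.0, np.empty((0, 2), dtype=np.int32)

    pairs = np.empty((bnp, 2), dtype=np.int32)
    k = int(bnp) - 1
    ci, cj, cs, cc = bi, bj, 1, bc
    while ci >= 0:
        pairs[k, 0] = ci
        pairs[k, 1] = jlo + cj
        k -= 1
        ni = Bi[ci, cj, cs, cc]
        nj = Bj[ci, cj, cs, cc]
        ns = Bs[ci, cj, cs, cc]
        nc = Bc[ci, cj, cs, cc]
        if ni == -1:
            break
        ci, cj, cs, cc = ni, nj, ns, nc
    if require_seed:
        # the forced 7-pair helix is a single DP root; expand it
        out = np.empty((int(bnp), 2), dtype=np.int32)
        for k2 in range(7):
            out[k2, 0] = k2
            out[k2, 1] = a0 - k2
        for k2 in range(7, int(bnp)):
            out[k2] = pairs[k2]
        pairs = out
    return True, best, pairs


@njit(cache=True)
def profile_dp(mi, ut, span, stack, b0, b1, ic0, ic1, init_e, term6):
    """Per-anchor minimum duplex energies over a whole UTR.

    Returns (e_all, e_12): for every anchor position the minimum admissible
    anchored energy over all structures, and over structures whose 5'-most
    pairing uses microRNA position 1 or 2.  INF where no structure exists.

    Requires affine bulge/interior penalties; loop runs are bounded by the
    search window (the caller guarantees the max_loop cap never binds).
    """
    L = ut.shape[0]
    m = mi.shape[0]
    e_all = np.full(L, INF)
    e_12 = np.full(L, INF)
    wmax = span + 1
    A = np.empty((m, wmax, 2, 24))
    BT = np.empty((m, 24))
    IN = np.empty((m, 24))
    RIN = np.empty(24)
    BM = np.empty(24)

    for a0 in range(L):
        jlo = a0 - span
        if jlo < 0:
            jlo = 0
        w = a0 - jlo + 1
        for i in range(m):
            for j in range(w):
                for s in range(2):
                    for cf in range(24):
                        A[i, j, s, cf] = INF
            for cf in range(24):
                BT[i, cf] = INF
                IN[i, cf] = INF

        for i0 in range(m):
            pt = PTYPE[mi[i0], ut[a0]]
            if pt >= 0 and pt < 4:
                f = 1 if i0 <= 1 else 0
                A[i0, w - 1, 0, 12 * f] = init_e + term6[pt]

        for jt in range(w - 2, -1, -1):
            js = jt + 2
            if js <= w - 1:
                for i in range(m):
                    pt = PTYPE[mi[i], ut[jlo + js]]
                    if pt < 0:
                        continue
                    te = term6[pt]
                    for cf in range(24):
                        v = A[i, js, 1, cf]
                        if v < BIG:
                            p = v + te + b1 * js
                            if p < BT[i, cf]:
                                BT[i, cf] = p
                            q = v + te + ic1 * (js - i)
                            if q < IN[i, cf]:
                                IN[i, cf] = q
            for cf in range(24):
                RIN[cf] = INF
                BM[cf] = INF
            for i2 in range(m):
                if i2 >= 2:
                    ii = i2 - 2
                    for cf in range(24):
                        if IN[ii, cf] < RIN[cf]:
                            RIN[cf] = IN[ii, cf]
                    pts = PTYPE[mi[ii], ut[jlo + jt + 1]]
                    if pts >= 0:
                        tes = term6[pts]
                        for cf in range(24):
                            v = A[ii, jt + 1, 1, cf]
                            if v < BIG:
                                p = v + tes - b1 * ii
                                if p < BM[cf]:
                                    BM[cf] = p
                pt2 = PTYPE[mi[i2], ut[jlo + jt]]
                if pt2 < 0:
                    continue
                gu2 = 1 if pt2 >= 4 else 0
                te2 = term6[pt2]
                if i2 >= 1:
                    pt1 = PTYPE[mi[i2 - 1], ut[jlo + jt + 1]]
                    if pt1 >= 0:
                        st = stack[pt1, pt2]
                        for cf in range(24):
                            cf2 = STEP24[cf, gu2]
                            if cf2 < 0:
                                continue
                            v = A[i2 - 1, jt + 1, 0, cf]
                            v1 = A[i2 - 1, jt + 1, 1, cf]
                            if v1 < v:
                                v = v1
                            if v < BIG:
                                cand = v + st
                                if cand < A[i2, jt, 1, cf2]:
                                    A[i2, jt, 1, cf2] = cand
                for cf in range(24):
                    cf2 = STEP24[cf, gu2]
                    if cf2 < 0:
                        continue
                    best = INF
                    if i2 >= 1:
                        v = BT[i2 - 1, cf]
                        if v < BIG:
                            cand = v + b0 - b1 * (jt + 2) + te2
                            if cand < best:
                                best = cand
                    v = BM[cf]
                    if v < BIG:
                        cand = v + b0 + b1 * (i2 - 2) + te2
                        if cand < best:
                            best = cand
                    v = RIN[cf]
                    if v < BIG:
                        cand = v + ic0 + ic1 * (i2 - jt - 4) + te2
                        if cand < best:
                            best = cand
                    if best < A[i2, jt, 0, cf2]:
                        A[i2, jt, 0, cf2] = best

        ea = INF
        e1 = INF
        for i in range(m):
            for j in range(w):
                pt = PTYPE[mi[i], ut[jlo + j]]
                if pt < 0:
                    continue
                te = term6[pt]
                for cf in range(24):
                    v = A[i, j, 1, cf]
                    if v < BIG:
                        tot = v + te
                        if tot < ea:
                            ea = tot
                        if cf >= 12 and tot < e1:
                            e1 = tot
        e_all[a0] = ea
        e_12[a0] = e1
    return e_all, e_12
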