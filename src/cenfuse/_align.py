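"""Affine-gap alignment kernels (numba).

All kernels optimise the lexicographic objective
``(score desc, matches desc, columns asc)`` so that the identity of the
returned alignment is a well-defined function of the input pair — in
particular symmetric under swapping query and target — even when several
alignments share the optimal score.

Encoding: 4-bit base-set masks (A=1, C=2, G=4, T=8; IUPAC codes are unions;
N and the scanner's mask sentinel are 0). Two codes match iff their sets
intersect, so N never matches anything, including N.
A gap of length L costs ``gap_open + (L-1) * gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2**40)


@njit(cache=False)
def _better(s1, m1, c1, s2, m2, c2):
    """True if triple 1 beats triple 2 under (score, matches, -columns)."""
    if s1 != s2:
        return s1 > s2
    if m1 != m2:
        return m1 > m2
    return c1 < c2


@njit(cache=False)
def _sw_forward(q, t, ma, mi, go, ge):
    """Local-alignment forward pass; returns best (score, matches, cols, qe, te).

    The end cell is the first (row-major) cell achieving the best triple.
    """
    m = q.shape[0]
    n = t.shape[0]
    hs = np.zeros(n + 1, dtype=np.int64)
    hm = np.zeros(n + 1, dtype=np.int64)
    hc = np.zeros(n + 1, dtype=np.int64)
    fs = np.full(n + 1, NEG, dtype=np.int64)
    fm = np.zeros(n + 1, dtype=np.int64)
    fc = np.zeros(n + 1, dtype=np.int64)
    best_s, best_m, best_c = 0, 0, 0
    best_i, best_j = 0, 0
    for i in range(1, m + 1):
        dh_s, dh_m, dh_c = hs[0], hm[0], hc[0]  # H[i-1][0]
        hs[0] = 0
        hm[0] = 0
        hc[0] = 0
        es, em, ec = NEG, 0, 0
        qi = q[i - 1]
        for j in range(1, n + 1):
            # E: gap in query (consume target), from left
            os_, om_, oc_ = hs[j - 1] + go, hm[j - 1], hc[j - 1] + 1
            xs_, xm_, xc_ = es + ge, em, ec + 1
            if _better(os_, om_, oc_, xs_, xm_, xc_):
                es, em, ec = os_, om_, oc_
            else:
                es, em, ec = xs_, xm_, xc_
            # F: gap in target (consume query), from above
            os_, om_, oc_ = hs[j] + go, hm[j], hc[j] + 1
            xs_, xm_, xc_ = fs[j] + ge, fm[j], fc[j] + 1
            if _better(os_, om_, oc_, xs_, xm_, xc_):
                fs[j], fm[j], fc[j] = os_, om_, oc_
            else:
                fs[j], fm[j], fc[j] = xs_, xm_, xc_
            # diagonal
            if (qi & t[j - 1]) != 0:
                ds = dh_s + ma
                dm = dh_m + 1
            else:
                ds = dh_s + mi
                dm = dh_m
            dc = dh_c + 1
            # H = best of diag, E, F, restart
            bs, bm, bc = 0, 0, 0
            if _better(ds, dm, dc, bs, bm, bc):
                bs, bm, bc = ds, dm, dc
            if _better(es, em, ec, bs, bm, bc):
                bs, bm, bc = es, em, ec
            if _better(fs[j], fm[j], fc[j], bs, bm, bc):
                bs, bm, bc = fs[j], fm[j], fc[j]
            dh_s, dh_m, dh_c = hs[j], hm[j], hc[j]
            hs[j], hm[j], hc[j] = bs, bm, bc
            if _better(bs, bm, bc, best_s, best_m, best_c):
                best_s, best_m, best_c = bs, bm, bc
                best_i, best_j = i, j
    return best_s, best_m, best_c, best_i, best_j


@njit(cache=False)
def _nw_origin_find(q, t, ma, mi, go, ge, ts_, tm_, tc_):
    """Global-from-origin pass; first row-major cell whose triple equals target."""
    m = q.shape[0]
    n = t.shape[0]
    hs = np.empty(n + 1, dtype=np.int64)
    hm = np.zeros(n + 1, dtype=np.int64)
    hc = np.empty(n + 1, dtype=np.int64)
    fs = np.full(n + 1, NEG, dtype=np.int64)
    fm = np.zeros(n + 1, dtype=np.int64)
    fc = np.zeros(n + 1, dtype=np.int64)
    hs[0] = 0
    hc[0] = 0
    for j in range(1, n + 1):
        hs[j] = go + (j - 1) * ge
        hc[j] = j
    for i in range(1, m + 1):
        dh_s, dh_m, dh_c = hs[0], hm[0], hc[0]
        hs[0] = go + (i - 1) * ge
        hm[0] = 0
        hc[0] = i
        es, em, ec = NEG, 0, 0
        qi = q[i - 1]
        for j in range(1, n + 1):
            os_, om_, oc_ = hs[j - 1] + go, hm[j - 1], hc[j - 1] + 1
            xs_, xm_, xc_ = es + ge, em, ec + 1
            if _better(os_, om_, oc_, xs_, xm_, xc_):
                es, em, ec = os_, om_, oc_
            else:
                es, em, ec = xs_, xm_, xc_
            os_, om_, oc_ = hs[j] + go, hm[j], hc[j] + 1
            xs_, xm_, xc_ = fs[j] + ge, fm[j], fc[j] + 1
            if _better(os_, om_, oc_, xs_, xm_, xc_):
                fs[j], fm[j], fc[j] = os_, om_, oc_
            else:
                fs[j], fm[j], fc[j] = xs_, xm_, xc_
            if (qi & t[j - 1]) != 0:
                ds = dh_s + ma
                dm = dh_m + 1
            else:
                ds = dh_s + mi
                dm = dh_m
            dc = dh_c + 1
            bs, bm, bc = ds, dm, dc
            if _better(es, em, ec, bs, bm, bc):
                bs, bm, bc = es, em, ec
            if _better(fs[j], fm[j], fc[j], bs, bm, bc):
                bs, bm, bc = fs[j], fm[j], fc[j]
            dh_s, dh_m, dh_c = hs[j], hm[j], hc[j]
            hs[j], hm[j], hc[j] = bs, bm, bc
            if bs == ts_ and bm == tm_ and bc == tc_:
                return i, j
    return -1, -1


@njit(cache=False)
def _nw_pointers(q, t, ma, mi, go, ge):
    """Full global alignment with pointer matrices; returns op codes.

    ops: 0 = diagonal, 1 = gap in query (consume target), 2 = gap in target
    (consume query).
    """
    m = q.shape[0]
    n = t.shape[0]
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.int8)
    hs = np.empty(n + 1, dtype=np.int64)
    hm = np.zeros(n + 1, dtype=np.int64)
    hc = np.empty(n + 1, dtype=np.int64)
    fs = np.full(n + 1, NEG, dtype=np.int64)
    fm = np.zeros(n + 1, dtype=np.int64)
    fc = np.zeros(n + 1, dtype=np.int64)
    hs[0] = 0
    hc[0] = 0
    for j in range(1, n + 1):
        hs[j] = go + (j - 1) * ge
        hc[j] = j
        ptr_h[0, j] = 1
        ptr_e[0, j] = 0 if j == 1 else 1
    for i in range(1, m + 1):
        dh_s, dh_m, dh_c = hs[0], hm[0], hc[0]
        hs[0] = go + (i - 1) * ge
        hm[0] = 0
        hc[0] = i
        ptr_h[i, 0] = 2
        ptr_f[i, 0] = 0 if i == 1 else 1
        es, em, ec = NEG, 0, 0
        qi = q[i - 1]
        for j in range(1, n + 1):
            os_, om_, oc_ = hs[j - 1] + go, hm[j - 1], hc[j - 1] + 1
            xs_, xm_, xc_ = es + ge, em, ec + 1
            if _better(os_, om_, oc_, xs_, xm_, xc_):
                es, em, ec = os_, om_, oc_
                ptr_e[i, j] = 0
            else:
                es, em, ec = xs_, xm_, xc_
                ptr_e[i, j] = 1
            os_, om_, oc_ = hs[j] + go, hm[j], hc[j] + 1
            xs_, xm_, xc_ = fs[j] + ge, fm[j], fc[j] + 1
            if _better(os_, om_, oc_, xs_, xm_, xc_):
                fs[j], fm[j], fc[j] = os_, om_, oc_
                ptr_f[i, j] = 0
            else:
                fs[j], fm[j], fc[j] = xs_, xm_, xc_
                ptr_f[i, j] = 1
            if (qi & t[j - 1]) != 0:
                ds = dh_s + ma
                dm = dh_m + 1
            else:
                ds = dh_s + mi
                dm = dh_m
            dc = dh_c + 1
            bs, bm, bc = ds, dm, dc
            ptr_h[i, j] = 0
            if _better(es, em, ec, bs, bm, bc):
                bs, bm, bc = es, em, ec
                ptr_h[i, j] = 1
            if _better(fs[j], fm[j], fc[j], bs, bm, bc):
                bs, bm, bc = fs[j], fm[j], fc[j]
                ptr_h[i, j] = 2
            dh_s, dh_m, dh_c = hs[j], hm[j], hc[j]
            hs[j], hm[j], hc[j] = bs, bm, bc
    # traceback
    ops = np.empty(m + n, dtype=np.int8)
    k = m + n
    i, j = m, n
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                k -= 1
                ops[k] = 0
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 1:
            k -= 1
            ops[k] = 1
            p = ptr_e[i, j]
            j -= 1
            state = 1 if p == 1 else 0
        else:
            k -= 1
            ops[k] = 2
            p = ptr_f[i, j]
            i -= 1
            state = 2 if p == 1 else 0
    return ops[k:]


def sw_locate(q, t, ma, mi, go, ge):
    """Best local alignment endpoints: (score, qs, qe, ts, te), 1-based."""
    s, mm, cc, qe, te = _sw_forward(q, t, ma, mi, go, ge)
    if s <= 0:
        return 0, 0, 0, 0, 0
    qr = np.ascontiguousarray(q[:qe][::-1])
    tr = np.ascontiguousarray(t[:te][::-1])
    i, j = _nw_origin_find(qr, tr, ma, mi, go, ge, s, mm, cc)
    if i < 0:  # pragma: no cover - internal consistency guard
        raise RuntimeError("alignment start not found; inconsistent DP passes")
    return int(s), qe - i + 1, qe, te - j + 1, te


def nw_traceback(q, t, ma, mi, go, ge):
    """Op codes of the optimal end-to-end alignment (see _nw_pointers)."""
    if q.shape[0] == 0 or t.shape[0] == 0:
        raise ValueError("cannot globally align an empty sequence")
    return _nw_pointers(q, t, ma, mi, go, ge)
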