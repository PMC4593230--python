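"""Numba kernel for global (Needleman-Wunsch) alignment with affine gaps.

Three-state Gotoh dynamic programming over encoded sequences
(A=0, C=1, G=2, T=3, N/other=4).  A gap run of length k costs
``gap_open + (k - 1) * gap_extend``.  Any column involving code 4 scores 0
(neutral): the distance stage excludes such columns anyway.

Scores are kept in rolling rows; only the three uint8 traceback matrices
are stored in full, so memory stays ~3*m*n bytes.  Traceback ties are
broken with a fixed priority — diagonal (match state) over up (gap in
the second sequence) over left — so alignments are reproducible across
runs and platforms.

An optional diagonal band (half-width ``band`` beyond the length
difference) restricts the DP to cells a global path could visit with at
most ``band`` surplus indel columns; with ``band < 0`` the full matrix
is filled.  For same-locus amplicons, whose optimal paths hug the
diagonal, a moderate band reproduces the unbanded optimum while cutting
time by an order of magnitude.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30

# state codes
_M, _X, _Y = 0, 1, 2  # match/mismatch, gap in b ("up"), gap in a ("left")


@njit(cache=False, nogil=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend, band):
    m, n = a.shape[0], b.shape[0]
    if band < 0:
        lo_off = -m - 1
        hi_off = n + 1
    else:
        lo_off = min(0, n - m) - band
        hi_off = max(0, n - m) + band
    tM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    Mp = np.full(n + 1, NEG)
    Xp = np.full(n + 1, NEG)
    Yp = np.full(n + 1, NEG)
    Mc = np.full(n + 1, NEG)
    Xc = np.full(n + 1, NEG)
    Yc = np.full(n + 1, NEG)
    Mp[0] = 0.0
    hi0 = min(n, hi_off)
    for j in range(1, hi0 + 1):
        Yp[j] = -(gap_open + (j - 1) * gap_extend)
        tY[0, j] = _Y if j > 1 else _M
    for i in range(1, m + 1):
        ai = a[i - 1]
        lo = max(1, i + lo_off)
        hi = min(n, i + hi_off)
        if lo == 1:
            Mc[0] = NEG
            Yc[0] = NEG
            Xc[0] = -(gap_open + (i - 1) * gap_extend)
            tX[i, 0] = _X if i > 1 else _M
        else:
            Mc[lo - 1] = NEG
            Xc[lo - 1] = NEG
            Yc[lo - 1] = NEG
        for j in range(lo, hi + 1):
            bj = b[j - 1]
            if ai >= 4 or bj >= 4:
                s = 0.0
            elif ai == bj:
                s = match
            else:
                s = mismatch
            # M state: priority M > X > Y on ties
            best = Mp[j - 1]
            src = _M
            if Xp[j - 1] > best:
                best = Xp[j - 1]
                src = _X
            if Yp[j - 1] > best:
                best = Yp[j - 1]
                src = _Y
            Mc[j] = best + s
            tM[i, j] = src
            # X state: consume a_i against a gap (vertical)
            best = Mp[j] - gap_open
            src = _M
            if Xp[j] - gap_extend > best:
                best = Xp[j] - gap_extend
                src = _X
            if Yp[j] - gap_open > best:
                best = Yp[j] - gap_open
                src = _Y
            Xc[j] = best
            tX[i, j] = src
            # Y state: consume b_j against a gap (horizontal)
            best = Mc[j - 1] - gap_open
            src = _M
            if Xc[j - 1] - gap_open > best:
                best = Xc[j - 1] - gap_open
                src = _X
            if Yc[j - 1] - gap_extend > best:
                best = Yc[j - 1] - gap_extend
                src = _Y
            Yc[j] = best
            tY[i, j] = src
        if hi < n:
            # invalidate the cell just beyond the band for the next row
            Mc[hi + 1] = NEG
            Xc[hi + 1] = NEG
            Yc[hi + 1] = NEG
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp
    # after the swap the last computed row is in *p
    state = _M
    score = Mp[n]
    if Xp[n] > score:
        score = Xp[n]
        state = _X
    if Yp[n] > score:
        score = Yp[n]
        state = _Y
    # traceback; path codes per column: 0 = diagonal, 1 = up, 2 = left
    path = np.empty(m + n, dtype=np.uint8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        if j == 0:
            state = _X
        elif i == 0:
            state = _Y
        if state == _M:
            prev = tM[i, j]
            path[k] = 0
            i -= 1
            j -= 1
        elif state == _X:
            prev = tX[i, j]
            path[k] = 1
            i -= 1
        else:
            prev = tY[i, j]
            path[k] = 2
            j -= 1
        k += 1
        state = prev
    return score, path[:k][::-1].copy()


def gotoh_align(a: np.ndarray, b: np.ndarray, match: float, mismatch: float,
                gap_open: float, gap_extend: float, band: int = -1):
    """Optimal global alignment of encoded sequences.

    Returns ``(score, path)`` where path codes per alignment column are
    0 = diagonal, 1 = gap in ``b``, 2 = gap in ``a``.  ``band >= 0``
    restricts the DP to a diagonal band of that half-width beyond the
    length difference.
    """
    return _gotoh(a, b, float(match), float(mismatch),
                  float(gap_open), float(gap_extend), int(band))
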