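"""Banded affine profile-profile alignment kernel (numba).

Scores are expected pairwise substitution scores between profile columns
(match +1, mismatch -1, computed from base frequencies; N and gap characters
contribute 0), with affine gaps: the first gap column costs ``gap_open`` and
each extension ``gap_extend``.  The band is given per row as a window start
array; out-of-band cells are -inf.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NINF = -1.0e30


@njit(cache=True)
def _align_banded(fa, sa, fb, sb, lo, width, gap_open, gap_extend):
    """Returns ops int8 array (0: col/col, 1: A col vs gap, 2: gap vs B col)."""
    la = fa.shape[0]
    lb = fb.shape[0]
    m = np.full((la + 1, width), NINF)
    x = np.full((la + 1, width), NINF)
    y = np.full((la + 1, width), NINF)
    pm = np.zeros((la + 1, width), dtype=np.int8)
    px = np.zeros((la + 1, width), dtype=np.int8)
    py = np.zeros((la + 1, width), dtype=np.int8)

    for i in range(la + 1):
        l = lo[i]
        for jj in range(width):
            j = l + jj
            if j > lb:
                break
            if i == 0 and j == 0:
                m[0, jj] = 0.0
                continue
            # substitution into (i, j)
            if i > 0 and j > 0:
                pj = (j - 1) - lo[i - 1]
                if 0 <= pj < width:
                    s = 2.0 * (
                        fa[i - 1, 0] * fb[j - 1, 0]
                        + fa[i - 1, 1] * fb[j - 1, 1]
                        + fa[i - 1, 2] * fb[j - 1, 2]
                        + fa[i - 1, 3] * fb[j - 1, 3]
                    ) - sa[i - 1] * sb[j - 1]
                    best = m[i - 1, pj]
                    ptr = 0
                    if x[i - 1, pj] > best:
                        best = x[i - 1, pj]
                        ptr = 1
                    if y[i - 1, pj] > best:
                        best = y[i - 1, pj]
                        ptr = 2
                    if best > NINF / 2:
                        m[i, jj] = best + s
                        pm[i, jj] = ptr
            # gap in B (consume column of A): from (i-1, j)
            if i > 0:
                pj = j - lo[i - 1]
                if 0 <= pj < width:
                    vo = m[i - 1, pj] + gap_open
                    ve = x[i - 1, pj] + gap_extend
                    vy = y[i - 1, pj] + gap_open
                    best = vo
                    ptr = 0
                    if ve > best:
                        best = ve
                        ptr = 1
                    if vy > best:
                        best = vy
                        ptr = 2
                    if best > NINF / 2:
                        x[i, jj] = best
                        px[i, jj] = ptr
            # gap in A (consume column of B): from (i, j-1)
            if jj > 0 or j - 1 >= lo[i]:
                pj = (j - 1) - lo[i]
                if 0 <= pj < width and j > 0:
                    vo = m[i, pj] + gap_open
                    vx = x[i, pj] + gap_open
                    ve = y[i, pj] + gap_extend
                    best = vo
                    ptr = 0
                    if vx > best:
                        best = vx
                        ptr = 1
                    if ve > best:
                        best = ve
                        ptr = 2
                    if best > NINF / 2:
                        y[i, jj] = best
                        py[i, jj] = ptr

    # traceback from (la, lb)
    jj = lb - lo[la]
    state = 0
    best = m[la, jj]
    if x[la, jj] > best:
        best = x[la, jj]
        state = 1
    if y[la, jj] > best:
        best = y[la, jj]
        state = 2
    ops = np.empty(la + lb, dtype=np.int8)
    nops = 0
    i = la
    j = lb
    while i > 0 or j > 0:
        jj = j - lo[i]
        if state == 0:
            ops[nops] = 0
            nops += 1
            state = pm[i, jj]
            i -= 1
            j -= 1
        elif state == 1:
            ops[nops] = 1
            nops += 1
            state = px[i, jj]
            i -= 1
        else:
            ops[nops] = 2
            nops += 1
            state = py[i, jj]
            j -= 1
    return ops[:nops][::-1].copy()


def align_profiles(
    counts_a: np.ndarray,
    rows_a: int,
    counts_b: np.ndarray,
    rows_b: int,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
    band: int | None = None,
) -> np.ndarray:
    """Align two profiles given per-column base counts (L, 5: A,C,G,T,N).

    Frequencies are counts over the number of rows; gap and N columns simply
    have less substitution mass.  Returns the op sequence (0/1/2 as above).
    """
    la, lb = counts_a.shape[0], counts_b.shape[0]
    fa = (counts_a[:, :4] / rows_a).astype(np.float64)
    fb = (counts_b[:, :4] / rows_b).astype(np.float64)
    sa = fa.sum(axis=1)
    sb = fb.sum(axis=1)
    if band is None:
        band = max(32, abs(la - lb) + 32)
    band = min(band, max(la, lb))
    # per-row window start along B, following the main diagonal
    i_idx = np.arange(la + 1, dtype=np.float64)
    center = np.round(i_idx * (lb / max(la, 1))).astype(np.int64)
    lo = np.maximum(0, center - band)
    width = int(2 * band + 2)
    lo = np.minimum(lo, np.maximum(0, lb + 1 - width))
    return _align_banded(fa, sa, fb, sb, lo, width, float(gap_open), float(gap_extend))
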