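"""Numba dynamic-programming kernels for the alignment engine.

Affine gap convention: a gap of length k costs ``gap_open + k * gap_extend``
(the first gap base pays both penalties), i.e. BLASTN-style accounting.
Sequences are int8 arrays with A,C,G,T,N coded 0..4; N never matches.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**8)


@njit(cache=True)
def local_dp(a, b, match, mismatch, gap_open, gap_extend):
    """Smith-Waterman with affine gaps; returns score matrices + best cell."""
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    ptr = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 up(E), 3 left(F)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i - 1, j] + gap_extend
            eo = H[i - 1, j] + gap_open + gap_extend
            if eo > e:
                e = eo
            f = F[i, j - 1] + gap_extend
            fo = H[i, j - 1] + gap_open + gap_extend
            if fo > f:
                f = fo
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            d = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, E, F, ptr


@njit(cache=True)
def traceback(a, b, H, E, F, ptr, bi, bj, gap_open, gap_extend):
    """Walk back from (bi, bj); returns (a_start, b_start, matches, columns)."""
    i = bi
    j = bj
    matches = 0
    cols = 0
    state = 0  # 0 in H, 1 in E (vertical gap), 2 in F (horizontal gap)
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if E[i, j] == H[i - 1, j] + gap_open + gap_extend:
                i -= 1
                state = 0
            else:
                i -= 1
        else:
            cols += 1
            if F[i, j] == H[i, j - 1] + gap_open + gap_extend:
                j -= 1
                state = 0
            else:
                j -= 1
    return i, j, matches, cols


@njit(cache=True)
def overlap_dp(a, b, match, mismatch, gap_open, gap_extend):
    """Overlap (free end-gap) alignment of fragment ``a`` against template ``b``.

    Both sequence overhangs are penalty-free; internal gaps are affine.
    Best cell is taken over the last row and last column.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i - 1, j] + gap_extend
            eo = H[i - 1, j] + gap_open + gap_extend
            if eo > e:
                e = eo
            f = F[i, j - 1] + gap_extend
            fo = H[i, j - 1] + gap_open + gap_extend
            if fo > f:
                f = fo
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            d = H[i - 1, j - 1] + s
            h = d
            p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            ptr[i, j] = p
    best = NEG
    bi = n
    bj = m
    for j in range(m + 1):
        if H[n, j] > best:
            best = H[n, j]
            bi = n
            bj = j
    for i in range(n + 1):
        if H[i, m] > best:
            best = H[i, m]
            bi = i
            bj = m
    return best, bi, bj, H, E, F, ptr


@njit(cache=True)
def overlap_traceback(a, b, H, E, F, ptr, bi, bj, gap_open, gap_extend):
    """Traceback for overlap_dp filling a fragment->template position map.

    Returns (a_start, b_start, matches, columns, mapping) where mapping[i]
    is the template index aligned to fragment base i, or -1 if the base is
    unaligned (overhang) or inserted relative to the template.
    """
    n = a.shape[0]
    mapping = np.full(n, -1, np.int64)
    i = bi
    j = bj
    matches = 0
    cols = 0
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 1:
                cols += 1
                mapping[i - 1] = j - 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if E[i, j] == H[i - 1, j] + gap_open + gap_extend:
                i -= 1
                state = 0
            else:
                i -= 1
        else:
            cols += 1
            if F[i, j] == H[i, j - 1] + gap_open + gap_extend:
                j -= 1
                state = 0
            else:
                j -= 1
    return i, j, matches, cols, mapping
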