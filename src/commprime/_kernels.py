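"""Numba DP kernels for local alignment.

Two kernels: a full Smith–Waterman matrix (the exact reference used by
:func:`commprime.homology.local_align`) and a banded variant restricted to a
diagonal window (used by the seeded many-against-many engine).  Both use
linear gap costs and store a pointer matrix for traceback; traceback itself is
done in Python on the tiny optimal path.

Pointer codes: 0 = stop, 1 = diagonal, 2 = up (gap in target), 3 = left
(gap in query).  Ties prefer diagonal, then up, then left; the best cell is
the first maximum in row-major order, so results are fully deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def sw_full(a, b, match, mismatch, gap):  # pragma: no cover - compiled
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    P = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = H[i - 1, j - 1] + s
            p = 1
            u = H[i - 1, j] + gap
            if u > h:
                h = u
                p = 2
            l = H[i, j - 1] + gap
            if l > h:
                h = l
                p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            P[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, P


@njit(cache=False)
def sw_banded(a, b, dlo, dhi, match, mismatch, gap):  # pragma: no cover
    m = a.shape[0]
    n = b.shape[0]
    w = dhi - dlo + 1
    H = np.zeros((m + 1, w), dtype=np.int32)
    P = np.zeros((m + 1, w), dtype=np.uint8)
    best = 0
    bi = 0
    bt = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for t in range(w):
            j = i + dlo + t
            if j < 1 or j > n:
                H[i, t] = 0
                P[i, t] = 0
                continue
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = H[i - 1, t] + s  # (i-1, j-1) sits at the same band index
            p = 1
            if t + 1 < w:
                u = H[i - 1, t + 1] + gap  # (i-1, j)
                if u > h:
                    h = u
                    p = 2
            if t - 1 >= 0:
                l = H[i, t - 1] + gap  # (i, j-1)
                if l > h:
                    h = l
                    p = 3
            if h <= 0:
                h = 0
                p = 0
            H[i, t] = h
            P[i, t] = p
            if h > best:
                best = h
                bi = i
                bt = t
    return best, bi, bt, P
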