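"""Affine-gap alignment kernels (Gotoh dynamic programming, numba-jit).

Gap cost convention: a gap of length L costs ``gap_open + L * gap_extend``
(the BLAST convention with defaults 11/1). Traceback ties are broken
deterministically: diagonal first, then up (gap in the second sequence),
then left (gap in the first sequence). Local tracebacks start from the
maximal cell with the smallest (i, j) in row-major order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(10**12))


@njit(cache=False)
def _fill_local(a, b, sub, go, ge):
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(E[i, j - 1] - ge, H[i, j - 1] - go - ge)
            f = max(F[i - 1, j] - ge, H[i - 1, j] - go - ge)
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            v = h
            if f > v:
                v = f
            if e > v:
                v = e
            if v < 0:
                v = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=False)
def _trace_local(a, b, sub, go, ge, H, E, F, bi, bj):
    """Return aligned index arrays (gap = -1), query start, subject start."""
    # worst case path length n+m
    qa = np.empty(a.shape[0] + b.shape[0], dtype=np.int64)
    sa = np.empty(a.shape[0] + b.shape[0], dtype=np.int64)
    k = 0
    i, j = bi, bj
    state = 0  # 0=H, 1=F(up), 2=E(left)
    while i > 0 or j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                qa[k] = i - 1
                sa[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = 2
            else:  # pragma: no cover - unreachable for consistent matrices
                break
        elif state == 1:
            qa[k] = i - 1
            sa[k] = -1
            k += 1
            if F[i, j] == H[i - 1, j] - go - ge:
                state = 0
            i -= 1
        else:
            qa[k] = -1
            sa[k] = j - 1
            k += 1
            if E[i, j] == H[i, j - 1] - go - ge:
                state = 0
            j -= 1
    return qa[:k][::-1].copy(), sa[:k][::-1].copy(), i, j


@njit(cache=False)
def _fill_global(a, b, sub, go, ge):
    n, m = a.shape[0], b.shape[0]
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = -(go + ge * j)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -(go + ge * i)
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(E[i, j - 1] - ge, H[i, j - 1] - go - ge)
            f = max(F[i - 1, j] - ge, H[i - 1, j] - go - ge)
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            v = h
            if f > v:
                v = f
            if e > v:
                v = e
            E[i, j] = e
            F[i, j] = f
            H[i, j] = v
    return H, E, F


@njit(cache=False)
def _trace_global(a, b, sub, go, ge, H, E, F):
    qa = np.empty(a.shape[0] + b.shape[0], dtype=np.int64)
    sa = np.empty(a.shape[0] + b.shape[0], dtype=np.int64)
    k = 0
    i, j = a.shape[0], b.shape[0]
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                qa[k] = i - 1
                sa[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            qa[k] = i - 1
            sa[k] = -1
            k += 1
            if F[i, j] == H[i - 1, j] - go - ge or i == 1:
                state = 0
            i -= 1
        else:
            qa[k] = -1
            sa[k] = j - 1
            k += 1
            if E[i, j] == H[i, j - 1] - go - ge or j == 1:
                state = 0
            j -= 1
    return qa[:k][::-1].copy(), sa[:k][::-1].copy()


def local_align(a: np.ndarray, b: np.ndarray, sub: np.ndarray, go: int, ge: int):
    """Optimal local alignment. Returns (score, qa_idx, sa_idx)."""
    H, E, F, best, bi, bj = _fill_local(a, b, sub, go, ge)
    if best == 0:
        return 0, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qa, sa, _, _ = _trace_local(a, b, sub, go, ge, H, E, F, bi, bj)
    return int(best), qa, sa


def local_score(a: np.ndarray, b: np.ndarray, sub: np.ndarray, go: int, ge: int) -> int:
    return int(_fill_local(a, b, sub, go, ge)[3])


def global_align(a: np.ndarray, b: np.ndarray, sub: np.ndarray, go: int, ge: int):
    """Optimal global alignment. Returns (score, qa_idx, sa_idx)."""
    H, E, F = _fill_global(a, b, sub, go, ge)
    qa, sa = _trace_global(a, b, sub, go, ge, H, E, F)
    return int(H[a.shape[0], b.shape[0]]), qa, sa
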