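"""Affine-gap (Gotoh) alignment kernel for profile-profile merges.

Operates on a precomputed column-score matrix so the same kernel serves
sequence-sequence, sequence-profile and profile-profile steps.  Tie-break
order is diagonal > up > left, which keeps progressive alignment
deterministic for a fixed input order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def _fill(S, gap_open, gap_extend):
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in B (consume A column)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in A (consume B column)
    # traceback state per matrix: 0=M, 1=Ix, 2=Iy
    tM = np.zeros((n + 1, m + 1), np.int8)
    tX = np.zeros((n + 1, m + 1), np.int8)
    tY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
        tX[i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
        tY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M
            best, state = M[i - 1, j - 1], 0
            if Ix[i - 1, j - 1] > best:
                best, state = Ix[i - 1, j - 1], 1
            if Iy[i - 1, j - 1] > best:
                best, state = Iy[i - 1, j - 1], 2
            M[i, j] = best + S[i - 1, j - 1]
            tM[i, j] = state
            # Ix: gap in B
            a = M[i - 1, j] + gap_open
            b = Ix[i - 1, j] + gap_extend
            if a >= b:
                Ix[i, j], tX[i, j] = a, 0
            else:
                Ix[i, j], tX[i, j] = b, 1
            # Iy: gap in A
            a = M[i, j - 1] + gap_open
            b = Iy[i, j - 1] + gap_extend
            if a >= b:
                Iy[i, j], tY[i, j] = a, 0
            else:
                Iy[i, j], tY[i, j] = b, 2
    return M, Ix, Iy, tM, tX, tY


@njit(cache=True)
def _traceback(M, Ix, Iy, tM, tX, tY, n, m):
    ops = np.empty(n + m, np.int8)  # 0=diag, 1=up, 2=left
    k = 0
    # choose final state (prefer M, then Ix, then Iy)
    state = 0
    best = M[n, m]
    if Ix[n, m] > best:
        best, state = Ix[n, m], 1
    if Iy[n, m] > best:
        best, state = Iy[n, m], 2
    score = best
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = tM[i, j]
            ops[k] = 0
            i -= 1
            j -= 1
        elif state == 1:
            prev = tX[i, j]
            ops[k] = 1
            i -= 1
        else:
            prev = tY[i, j]
            ops[k] = 2
            j -= 1
        state = prev
        k += 1
    return score, ops[:k][::-1].copy()


def align_profiles(score_matrix: np.ndarray, gap_open: float,
                   gap_extend: float) -> tuple[float, np.ndarray]:
    """Optimal global alignment over a column-score matrix.

    Returns (score, ops) with ops in {0: match columns, 1: gap in the second
    profile, 2: gap in the first profile}.
    """
    S = np.ascontiguousarray(score_matrix, dtype=np.float64)
    M, Ix, Iy, tM, tX, tY = _fill(S, float(gap_open), float(gap_extend))
    return _traceback(M, Ix, Iy, tM, tX, tY, S.shape[0], S.shape[1])
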