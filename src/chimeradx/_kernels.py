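"""Compiled dynamic-programming kernels for sequence and profile alignment.

All kernels fill Gotoh three-state affine-gap DP tables and return the
score plus int8 pointer tensors; tracebacks are reconstructed in Python.
A gap of length k costs ``gap_open + k * gap_extend``.

State codes: 0 = M (diagonal), 1 = X (consume row sequence / profile
column, gap in the other), 2 = Y (consume column sequence).  Pointer values
give the state the move came from; ties are broken M > X > Y so tracebacks
are bit-stable.
"""

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=False)
def gotoh_global(a, b, sub, gap_open, gap_extend):
    """Global affine alignment of index-encoded sequences a, b.

    Returns (score, end_state, ptr) with ptr shape (3, n+1, m+1).
    """
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - i * gap_extend
        ptr[1, i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - j * gap_extend
        ptr[2, 0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            # M state: ties prefer M > X > Y
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            ptr[0, i, j] = p
            # X: gap in b (consume a)
            open_x = M[i - 1, j] - gap_open - gap_extend
            ext_x = X[i - 1, j] - gap_extend
            if open_x >= ext_x:
                X[i, j] = open_x
                ptr[1, i, j] = 0
            else:
                X[i, j] = ext_x
                ptr[1, i, j] = 1
            # Y: gap in a (consume b)
            open_y = M[i, j - 1] - gap_open - gap_extend
            ext_y = Y[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Y[i, j] = open_y
                ptr[2, i, j] = 0
            else:
                Y[i, j] = ext_y
                ptr[2, i, j] = 2
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    return score, state, ptr


@njit(cache=False)
def gotoh_profile_global(col_scores, seq, gap_open, gap_extend):
    """Global profile-to-sequence alignment.

    ``col_scores`` has shape (n_cols, n_symbols); rows of the DP consume
    profile columns, columns consume sequence residues.  Skipping a profile
    column or inserting a residue both pay affine penalties.
    """
    n = col_scores.shape[0]
    m = seq.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - i * gap_extend
        ptr[1, i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - j * gap_extend
        ptr[2, 0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = col_scores[i - 1, seq[j - 1]]
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            ptr[0, i, j] = p
            open_x = M[i - 1, j] - gap_open - gap_extend
            ext_x = X[i - 1, j] - gap_extend
            if open_x >= ext_x:
                X[i, j] = open_x
                ptr[1, i, j] = 0
            else:
                X[i, j] = ext_x
                ptr[1, i, j] = 1
            open_y = M[i, j - 1] - gap_open - gap_extend
            ext_y = Y[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Y[i, j] = open_y
                ptr[2, i, j] = 0
            else:
                Y[i, j] = ext_y
                ptr[2, i, j] = 2
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    return score, state, ptr


@njit(cache=False)
def gotoh_profile_local(col_scores, seq, gap_open, gap_extend):
    """Smith-Waterman-style local profile-to-sequence alignment.

    Returns (score, end_i, end_j, start_i, start_j): the maximal segment
    score and its envelope in profile (i) and sequence (j) coordinates,
    1-based inclusive; all zeros when no cell scores positive.  Ties on the
    best cell prefer the smallest (end_i, end_j).
    """
    n = col_scores.shape[0]
    m = seq.shape[0]
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    # origin (start cell) of the local path ending in each state, row-major
    # encoded as i * (m + 2) + j so comparison is lexicographic on (i, j)
    oM = np.zeros((n + 1, m + 1), dtype=np.int64)
    oX = np.zeros((n + 1, m + 1), dtype=np.int64)
    oY = np.zeros((n + 1, m + 1), dtype=np.int64)
    stride = m + 2
    best = 0.0
    bi = 0
    bj = 0
    borigin = np.int64((n + 1) * stride)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = col_scores[i - 1, seq[j - 1]]
            prev = M[i - 1, j - 1]
            org = oM[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                org = oX[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                org = oY[i - 1, j - 1]
            if prev <= 0.0:
                prev = 0.0
                org = np.int64(i * stride + j)  # path starts at this match
            val = prev + s
            if val <= 0.0:
                M[i, j] = 0.0
                oM[i, j] = np.int64(i * stride + j)
            else:
                M[i, j] = val
                oM[i, j] = org
                if val > best or (val == best and org < borigin):
                    best = val
                    bi = i
                    bj = j
                    borigin = org
            open_x = M[i - 1, j] - gap_open - gap_extend
            ext_x = X[i - 1, j] - gap_extend
            if open_x >= ext_x:
                X[i, j] = open_x
                oX[i, j] = oM[i - 1, j]
            else:
                X[i, j] = ext_x
                oX[i, j] = oX[i - 1, j]
            open_y = M[i, j - 1] - gap_open - gap_extend
            ext_y = Y[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Y[i, j] = open_y
                oY[i, j] = oM[i, j - 1]
            else:
                Y[i, j] = ext_y
                oY[i, j] = oY[i, j - 1]
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0
    si = int(borigin // stride)
    sj = int(borigin % stride)
    return best, bi, bj, si, sj
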