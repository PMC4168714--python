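"""Numba inner loops: the affine-gap DP fill and the Nussinov fill.

Kept separate so the hot loops stay simple scalar code; all bookkeeping
(traceback, scoring tables, tie-breaking policy) lives in the calling
modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30  # -inf sentinel that survives arithmetic inside the DP


@njit
def fill_dp(match: np.ndarray, gap_open: float, gap_extend: float):
    """Fill the three-matrix semi-global affine-gap DP.

    ``match[i-1, j-1]`` is the full match term (structural + sequence) for
    aligning profile column i to target position j.  Initialization:
    M[0,0] = 0, M[i,0] = open + i*extend, M[0,j] = 0 (free target prefix),
    D[0,j] = I[i,0] = -inf.  A gap of length L costs open + L*extend.
    """
    n, m = match.shape
    D = np.full((n + 1, m + 1), NEG_INF)
    I = np.full((n + 1, m + 1), NEG_INF)
    M = np.empty((n + 1, m + 1))
    M[0, :] = 0.0
    for i in range(1, n + 1):
        M[i, 0] = gap_open + i * gap_extend
        D[i, 0] = gap_open + i * gap_extend
        for j in range(1, m + 1):
            d = max(M[i - 1, j] + gap_open + gap_extend, D[i - 1, j] + gap_extend)
            ins = max(M[i, j - 1] + gap_open + gap_extend, I[i, j - 1] + gap_extend)
            D[i, j] = d
            I[i, j] = ins
            diag = M[i - 1, j - 1] + match[i - 1, j - 1]
            best = diag
            if d > best:
                best = d
            if ins > best:
                best = ins
            M[i, j] = best
    return D, I, M


@njit
def nussinov_fill(codes: np.ndarray, min_sep: int) -> np.ndarray:
    """Base-pair maximization counts N[i, j]; pairs require j - i >= min_sep.

    Codes: A=0, C=1, G=2, U=3 (anything else cannot pair).  Canonical pairs
    including GU wobble: code sums 3 (AU, GC) and 5 (GU).
    """
    L = len(codes)
    N = np.zeros((L, L), dtype=np.int64)
    for span in range(min_sep, L):
        for i in range(L - span):
            j = i + span
            best = N[i, j - 1]
            cj = codes[j]
            for k in range(i, j - min_sep + 1):
                ck = codes[k]
                if ck < 0 or cj < 0:
                    continue
                s = ck + cj
                if s == 3 or s == 5:
                    v = N[k + 1, j - 1] + 1
                    if k > i:
                        v += N[i, k - 1]
                    if v > best:
                        best = v
            N[i, j] = best
    return N
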