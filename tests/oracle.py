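"""Independent brute-force oracle for semi-global affine-gap alignment.

Enumerates every monotone matching of profile columns to target positions
(strictly increasing in both coordinates) and scores it directly:
match terms for matched pairs, affine gap cost (open + L*extend per
maximal run) for deleted columns, for inserted target bases between
matches, and for leading/trailing deleted columns; the target's flanks
outside the matched span are free.  The maximum over all matchings is the
optimal semi-global score.  No dynamic programming is used, so this is an
independent check of the DP engine.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def _gap_cost(length: int, gap_open: float, gap_extend: float) -> float:
    return 0.0 if length == 0 else gap_open + length * gap_extend


def brute_force_semiglobal(match: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best score over all alignments that consume the full profile.

    ``match[i, j]`` is the score of aligning profile column i (0-based) to
    target position j.
    """
    n, m = match.shape
    best = _gap_cost(n, gap_open, gap_extend)  # whole profile deleted
    for k in range(1, min(n, m) + 1):
        for cols in combinations(range(n), k):
            for poss in combinations(range(m), k):
                score = _gap_cost(cols[0], gap_open, gap_extend)  # leading deletions
                score += _gap_cost(n - 1 - cols[-1], gap_open, gap_extend)
                for t in range(k):
                    score += match[cols[t], poss[t]]
                    if t > 0:
                        d_cols = cols[t] - cols[t - 1] - 1
                        d_pos = poss[t] - poss[t - 1] - 1
                        score += _gap_cost(d_cols, gap_open, gap_extend)
                        score += _gap_cost(d_pos, gap_open, gap_extend)
                if score > best:
                    best = score
    return best


def brute_force_nussinov(seq: str, min_sep: int = 4) -> int:
    """Maximum number of nested canonical pairs by exhaustive recursion."""
    canonical = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

    def rec(i: int, j: int) -> int:
        if j - i < min_sep:
            return 0
        best = rec(i, j - 1)
        for k in range(i, j - min_sep + 1):
            if (seq[k], seq[j]) in canonical:
                cand = rec(k + 1, j - 1) + 1 + (rec(i, k - 1) if k > i else 0)
                best = max(best, cand)
        return best

    return rec(0, len(seq) - 1) if seq else 0
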