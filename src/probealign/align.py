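"""The core alignment engine.

Aligns a family profile against a reactivity-annotated target with a
three-matrix semi-global affine-gap dynamic program.  The match term for
profile column i and target position j is

    alpha * tau(s_i, r_j)  +  beta * sigma(p_i, b_j)

where tau is the structural similarity from the probing reactivity (0 when
r_j is undefined) and sigma is the profile-to-base substitution score.  The
alignment is semi-global (glocal): the full profile must be consumed, the
target's flanks are free (M[0, j] = 0, final score = max_j M[n, j]).

After traceback, a structure-consistency bonus rewards consensus pairs
whose two aligned target bases can form a canonical pair (AU, UA, GC, CG,
GU, UG) — separating true structural homologs from high-scoring sequence
matches.  The bonus is added after the DP, never inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import fill_dp
from .io import ALPHABET, ReactivityTrack
from .profiles import PROFILE_SYMBOLS, Profile
from .reactivity import StructuralScoringConfig, tau_table

__all__ = [
    "AlignParams",
    "AlignmentHit",
    "default_subst_matrix",
    "sigma",
    "align",
    "consistency_score",
    "scan",
]

CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


def default_subst_matrix() -> dict[tuple[str, str], float]:
    """+2 match / -1 mismatch over {A,C,G,U}; X scores 0; gap row -1."""
    table: dict[tuple[str, str], float] = {}
    for x in PROFILE_SYMBOLS:
        for y in ALPHABET:
            if x == "X" or y == "X":
                table[(x, y)] = 0.0
            elif x == "-":
                table[(x, y)] = -1.0
            else:
                table[(x, y)] = 2.0 if x == y else -1.0
    return table


@dataclass(frozen=True)
class AlignParams:
    """All scoring knobs for one search run.

    alpha/beta weight the structural and sequence similarity terms; gap
    penalties are non-positive with affine cost open + L*extend for a
    length-L gap.  ``consistency_bonus`` is added per consistent canonical
    pair to the combined score when ``use_consistency`` is on.
    """

    alpha: float = 0.7
    beta: float = 2.6
    gap_open: float = -4.0
    gap_extend: float = -1.0
    subst: dict = field(default_factory=default_subst_matrix)
    scoring: StructuralScoringConfig = field(default_factory=StructuralScoringConfig)
    consistency_bonus: float = 1.0
    use_consistency: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.consistency_bonus < 0:
            raise ValueError("consistency_bonus must be >= 0")

    def subst_array(self) -> np.ndarray:
        """(6, 5) array view of the substitution table, symbol-ordered."""
        arr = np.empty((6, 5))
        for xi, x in enumerate(PROFILE_SYMBOLS):
            for yi, y in enumerate(ALPHABET):
                arr[xi, yi] = self.subst[(x, y)]
        return arr


@dataclass
class AlignmentHit:
    """One scored alignment of a profile against a target region."""

    query_id: str
    target_id: str
    target_start: int  # 1-based inclusive
    target_end: int  # 1-based inclusive
    dp_score: float
    consistency_score: float
    combined_score: float
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.target_start > self.target_end:
            raise ValueError("target_start must be <= target_end")


def sigma(column: np.ndarray, base: str, subst: dict[tuple[str, str], float]) -> float:
    """Expected substitution score of one profile column against one base.

    sigma(p_i, b) = sum_x v_i^x * m(x, b) over x in {A,C,G,U,X,-}.
    """
    return float(sum(column[k] * subst[(x, base)] for k, x in enumerate(PROFILE_SYMBOLS)))


def _encode(seq: str) -> np.ndarray:
    codes = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        codes[i] = ALPHABET.index(c) if c in ALPHABET else 4
    return codes


def match_matrix(
    profile: Profile, target: str, track: ReactivityTrack, params: AlignParams
) -> np.ndarray:
    """(n, m) match terms alpha*tau + beta*sigma for the DP."""
    codes = _encode(target)
    sig = profile.freqs @ params.subst_array()  # (n, 5)
    seq_part = sig[:, codes]
    struct_part = tau_table(
        profile.pairedness, track.values, track.defined_mask, params.scoring
    )
    return params.alpha * struct_part + params.beta * seq_part


def align(
    profile: Profile,
    target: str,
    track: ReactivityTrack | None = None,
    params: AlignParams | None = None,
    target_id: str = "target",
) -> AlignmentHit:
    """Best semi-global alignment of the full profile within the target.

    Traceback starts from the smallest target column achieving the best end
    score and prefers match over deletion over insertion at score ties, so
    output is deterministic.  Reactivities belong to the target: deleted
    profile columns consume none, and target bases skipped by insertions
    contribute no structural score.
    """
    if params is None:
        params = AlignParams()
    if profile.n == 0:
        raise ValueError("empty profile")
    if len(target) == 0:
        raise ValueError("empty target")
    if track is None:
        track = ReactivityTrack.undefined(len(target))
    if len(track) != len(target):
        raise ValueError("reactivity track length must equal target length")

    mm = match_matrix(profile, target, track, params)
    D, I, M = fill_dp(mm, params.gap_open, params.gap_extend)
    n, m = profile.n, len(target)

    end_j = int(np.argmax(M[n, :]))  # argmax returns the first (smallest j) on ties
    dp_score = float(M[n, end_j])

    aligned_pairs = _traceback(D, I, M, mm, params, end_j)

    if aligned_pairs:
        start0 = min(p[1] for p in aligned_pairs)
        end0 = max(p[1] for p in aligned_pairs)
    else:
        # degenerate: the whole profile deleted; pin an empty-width anchor
        start0 = end0 = max(end_j - 1, 0)
    hit = AlignmentHit(
        query_id=profile.query_id,
        target_id=target_id,
        target_start=start0 + 1,
        target_end=end0 + 1,
        dp_score=dp_score,
        consistency_score=0.0,
        combined_score=dp_score,
        aligned_pairs=aligned_pairs,
    )
    cs = consistency_score(hit, profile, target, params.consistency_bonus)
    hit.consistency_score = cs
    if params.use_consistency:
        hit.combined_score = dp_score + cs
    return hit


def _traceback(D, I, M, mm, params, end_j) -> list[tuple[int, int]]:
    """Recover the matched (column, position) pairs; ties: match > del > ins."""
    go, ge = params.gap_open, params.gap_extend
    n = M.shape[0] - 1
    i, j = n, end_j
    state = "M"
    pairs: list[tuple[int, int]] = []
    while i > 0:
        if state == "M":
            if j > 0 and M[i, j] == M[i - 1, j - 1] + mm[i - 1, j - 1]:
                pairs.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif M[i, j] == D[i, j]:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            if D[i, j] == M[i - 1, j] + go + ge:
                state = "M"
            i -= 1
        else:  # I
            if I[i, j] == M[i, j - 1] + go + ge:
                state = "M"
            j -= 1
    pairs.reverse()
    return pairs


def consistency_score(
    hit: AlignmentHit, profile: Profile, target: str, bonus: float = 1.0
) -> float:
    """Structure-consistency bonus of a completed alignment.

    For every consensus pair (i, i') whose both columns are matched to
    target positions, add ``bonus`` when the two target bases form a
    canonical pair.  X never pairs.  Each pair is counted once.
    """
    if not profile.pair_table:
        return 0.0
    col_to_pos = dict(hit.aligned_pairs)
    total = 0.0
    for i, ip in profile.pair_table.items():
        if i < ip and i in col_to_pos and ip in col_to_pos:
            bi, bj = target[col_to_pos[i]], target[col_to_pos[ip]]
            if (bi, bj) in CANONICAL_PAIRS:
                total += bonus
    return total


def scan(
    profile: Profile,
    target: str,
    track: ReactivityTrack | None = None,
    params: AlignParams | None = None,
    max_hits: int = 10,
    min_separation: int = 0,
    target_id: str = "target",
) -> list[AlignmentHit]:
    """Greedy multi-hit scan of a long target.

    Repeatedly takes the best alignment, masks its span (bases to X,
    reactivities to undefined, plus ``min_separation`` flanking positions)
    and realigns, until ``max_hits`` hits are found or no positive-scoring
    hit remains.  Returned hits do not overlap.
    """
    if params is None:
        params = AlignParams()
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    if track is None:
        track = ReactivityTrack.undefined(len(target))

    masked_seq = list(target)
    masked_vals = track.values.copy()
    masked_mask = track.defined_mask.copy()
    taken: list[tuple[int, int]] = []  # 0-based half-open spans
    hits: list[AlignmentHit] = []
    for _ in range(4 * max_hits):  # progress bound: every round masks new span
        if len(hits) >= max_hits:
            break
        cur_track = ReactivityTrack(masked_vals.copy(), masked_mask.copy())
        hit = align(profile, "".join(masked_seq), cur_track, params, target_id=target_id)
        if hit.combined_score <= 0:
            break
        s0, e0 = hit.target_start - 1, hit.target_end  # half-open
        overlaps = any(s0 < te and ts < e0 for ts, te in taken)
        if not overlaps:
            hits.append(hit)
        taken.append((s0, e0))
        lo = max(0, s0 - min_separation)
        hi = min(len(target), e0 + min_separation)
        for k in range(lo, hi):
            masked_seq[k] = "X"
            masked_vals[k] = np.nan
            masked_mask[k] = False
    return hits
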