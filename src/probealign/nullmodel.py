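"""Score calibration against random decoys.

p-values for alignment scores are computed from a null distribution built
by aligning the query profile against random RNA decoys: sequences are
sampled from a stochastic context-free grammar (so they carry plausible
local pairing structure), each decoy is folded by base-pair maximization to
assign a secondary structure, reactivities concordant with that structure
are simulated from the configured conditional densities, and the profile
is aligned against each decoy.  The resulting scores are fitted with four
candidate distributions (normal, Gumbel, GEV, Gamma) by maximum likelihood;
goodness of fit is recorded as Kolmogorov-Smirnov statistics.  The Gamma
fit (location-shifted to cover negative scores) is always the one used for
p-values; the four-way comparison is retained as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._kernels import nussinov_fill
from .align import AlignParams, align
from .io import ReactivityTrack
from .profiles import Profile
from .reactivity import ReactivityDensityModel, default_shape_model

__all__ = [
    "DecoySpec",
    "GammaNull",
    "generate_decoy",
    "assign_structure",
    "simulate_reactivities",
    "sample_null_scores",
    "fit_null",
    "p_value",
    "calibrate",
]

#: Minimum sequence separation for a base pair (hairpin loop >= 3 nt).
MIN_PAIR_SEPARATION = 4


@dataclass(frozen=True)
class DecoySpec:
    """Decoy generation settings: segment count/length, GC content, seed."""

    n_segments: int = 5
    segment_length: int = 200
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_segments < 1 or self.segment_length < 1:
            raise ValueError("segment count and length must be positive")


# Stochastic CFG:  S -> xSy | xS | eps   with pair emissions (GC/CG, AU/UA,
# GU/UG wobble) and unpaired emissions.  Emission identities are tuned so
# the expected GC fraction equals the requested one exactly: unpaired bases
# are G/C with probability gc, and pair types contribute 2*p_gc + p_gu = 2*gc
# G/C nucleotides per pair.
_P_PAIR = 0.4  # probability of a pair production (before termination)
_P_WOBBLE = 0.1  # share of pair productions that are GU/UG


def _segment_from_grammar(length: int, gc: float, rng: np.random.Generator) -> str:
    p_gc_pair = max(0.0, min(1.0 - _P_WOBBLE, gc - _P_WOBBLE / 2))
    p_au_pair = 1.0 - _P_WOBBLE - p_gc_pair
    # left/right emitted slots; expand nonterminals until enough terminals
    out: list[str | None] = []  # None marks the open nonterminal slot
    left: list[str] = []
    right: list[str] = []  # reversed order
    while len(left) + len(right) < length:
        if rng.random() < _P_PAIR:
            u = rng.random()
            if u < p_gc_pair:
                pair = ("G", "C") if rng.random() < 0.5 else ("C", "G")
            elif u < p_gc_pair + p_au_pair:
                pair = ("A", "U") if rng.random() < 0.5 else ("U", "A")
            else:
                pair = ("G", "U") if rng.random() < 0.5 else ("U", "G")
            left.append(pair[0])
            right.append(pair[1])
        else:
            u = rng.random()
            if u < gc:
                base = "G" if rng.random() < 0.5 else "C"
            else:
                base = "A" if rng.random() < 0.5 else "U"
            left.append(base)
    seq = "".join(left) + "".join(reversed(right))
    return seq[:length]


def generate_decoy(spec: DecoySpec) -> str:
    """Concatenation of independently sampled stochastic-CFG segments.

    Deterministic given the spec's seed; output alphabet is {A,C,G,U}; the
    realized GC fraction is the requested one in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    return "".join(
        _segment_from_grammar(spec.segment_length, spec.gc_content, rng)
        for _ in range(spec.n_segments)
    )


def assign_structure(sequence: str) -> tuple[np.ndarray, dict[int, int]]:
    """Nested structure by base-pair maximization (canonical pairs incl. GU).

    Returns (pairedness flags with 0 = paired / 1 = unpaired, 0-based pair
    table).  Hairpin loops shorter than 3 nt are disallowed; traceback
    tie-breaking is fixed (leave the right end unpaired first, then the
    smallest pairing partner), so output is deterministic.
    """
    codes = np.array(
        ["ACGU".index(c) if c in "ACGU" else -10 for c in sequence], dtype=np.int64
    )
    L = len(codes)
    pair_table: dict[int, int] = {}
    if L > MIN_PAIR_SEPARATION:
        N = nussinov_fill(codes, MIN_PAIR_SEPARATION)
        stack = [(0, L - 1)]
        while stack:
            i, j = stack.pop()
            if j - i < MIN_PAIR_SEPARATION:
                continue
            if N[i, j] == N[i, j - 1]:
                stack.append((i, j - 1))
                continue
            for k in range(i, j - MIN_PAIR_SEPARATION + 1):
                s = codes[k] + codes[j]
                if codes[k] < 0 or codes[j] < 0 or (s != 3 and s != 5):
                    continue
                v = N[k + 1, j - 1] + 1 + (N[i, k - 1] if k > i else 0)
                if v == N[i, j]:
                    pair_table[k] = j
                    pair_table[j] = k
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    pairedness = np.ones(L, dtype=np.int8)
    for i in pair_table:
        pairedness[i] = 0
    return pairedness, pair_table


def simulate_reactivities(
    pairedness: np.ndarray,
    model: ReactivityDensityModel | None = None,
    seed: int = 0,
) -> ReactivityTrack:
    """Draw one reactivity per position from the matching conditional density.

    Paired positions sample from p(r | paired), unpaired from
    p(r | unpaired), i.i.d.; every position is defined.  Deterministic given
    the seed.
    """
    if model is None:
        model = default_shape_model()
    pairedness = np.asarray(pairedness)
    rng = np.random.default_rng(seed)
    values = np.empty(len(pairedness), dtype=float)
    paired_idx = np.flatnonzero(pairedness == 0)
    unpaired_idx = np.flatnonzero(pairedness != 0)
    # fixed draw order (paired first) keeps the track seed-reproducible
    values[paired_idx] = model.density_paired.sample(len(paired_idx), rng)
    values[unpaired_idx] = model.density_unpaired.sample(len(unpaired_idx), rng)
    return ReactivityTrack(values, np.ones(len(pairedness), dtype=bool))


def sample_null_scores(
    profile: Profile,
    spec: DecoySpec,
    params: AlignParams | None = None,
    n_samples: int = 1000,
) -> np.ndarray:
    """Combined scores of the profile against independent structured decoys.

    Each sample aligns the profile against one fresh decoy segment of length
    max(2 * profile length, spec.segment_length) carrying reactivities
    simulated from its own predicted structure, so samples are i.i.d.
    Deterministic given spec.seed.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if params is None:
        params = AlignParams()
    model = params.scoring.model or default_shape_model()
    seg_len = max(2 * profile.n, spec.segment_length)
    root = np.random.default_rng(spec.seed)
    # pre-drawn child seeds keep each decoy independent and reproducible
    seeds = root.integers(0, 2**31 - 1, size=(n_samples, 2))
    scores = np.empty(n_samples)
    for k in range(n_samples):
        seq_rng = np.random.default_rng(seeds[k, 0])
        seq = _segment_from_grammar(seg_len, spec.gc_content, seq_rng)
        pairedness, _ = assign_structure(seq)
        track = simulate_reactivities(pairedness, model, seed=int(seeds[k, 1]))
        scores[k] = align(profile, seq, track, params).combined_score
    return scores


@dataclass
class GammaNull:
    """A location-shifted Gamma null for alignment scores.

    shape k and scale theta are the Gamma parameters; mu shifts the support
    just below the smallest calibration score so negative scores are
    covered.  ``fit_report`` holds the K-S statistic of each candidate
    distribution (normal, gumbel, gev, gamma); ``ks_statistic`` is the
    Gamma's.
    """

    shape: float
    scale: float
    loc: float
    n_scores: int
    ks_statistic: float
    fit_report: dict[str, float]
    seed: int | None = None
    profile_id: str | None = None

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma shape and scale must be positive")

    def to_dict(self) -> dict:
        return {
            "profile_id": self.profile_id,
            "k": self.shape,
            "theta": self.scale,
            "mu": self.loc,
            "n_scores": self.n_scores,
            "ks": dict(self.fit_report),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GammaNull":
        return cls(
            shape=d["k"],
            scale=d["theta"],
            loc=d["mu"],
            n_scores=d["n_scores"],
            ks_statistic=d["ks"]["gamma"],
            fit_report=dict(d["ks"]),
            seed=d.get("seed"),
            profile_id=d.get("profile_id"),
        )


def fit_null(scores: np.ndarray, profile_id: str | None = None, seed: int | None = None) -> GammaNull:
    """Fit the four candidate nulls by ML and return the Gamma one.

    The Gamma is three-parameter (location-shifted) so negative scores are
    covered: the location is free in the ML fit, falling back to an anchor
    just below the sample minimum (mu = min - 1e-6 * range) if the free fit
    fails or leaves the smallest score outside the support.  All four K-S
    statistics are retained in the report; the Gamma is used for p-values
    regardless of which candidate wins.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 100:
        raise ValueError("need at least 100 scores to fit a null")
    rng_span = float(scores.max() - scores.min())
    if rng_span == 0:
        raise ValueError("degenerate null: zero score variance")

    report: dict[str, float] = {}
    n_loc, n_scale = stats.norm.fit(scores)
    report["normal"] = stats.kstest(scores, "norm", args=(n_loc, n_scale)).statistic
    g_loc, g_scale = stats.gumbel_r.fit(scores)
    report["gumbel"] = stats.kstest(scores, "gumbel_r", args=(g_loc, g_scale)).statistic
    gev_c, gev_loc, gev_scale = stats.genextreme.fit(
        scores, 0.1, loc=float(scores.mean()), scale=float(scores.std())
    )
    report["gev"] = stats.kstest(
        scores, "genextreme", args=(gev_c, gev_loc, gev_scale)
    ).statistic

    anchor = float(scores.min()) - 1e-6 * rng_span
    try:
        k, mu, theta = stats.gamma.fit(scores)
        if not (np.isfinite([k, mu, theta]).all() and k > 0 and theta > 0 and mu < scores.min()):
            raise ValueError
    except Exception:
        k, _, theta = stats.gamma.fit(scores, floc=anchor)
        mu = anchor
    report["gamma"] = stats.kstest(scores, "gamma", args=(k, mu, theta)).statistic

    return GammaNull(
        shape=float(k),
        scale=float(theta),
        loc=mu,
        n_scores=len(scores),
        ks_statistic=report["gamma"],
        fit_report=report,
        seed=seed,
        profile_id=profile_id,
    )


def p_value(score: float, null: GammaNull) -> float:
    """Upper-tail probability P(X >= score) under the shifted Gamma."""
    p = stats.gamma.sf(score, null.shape, loc=null.loc, scale=null.scale)
    return float(np.clip(p, 0.0, 1.0))


def calibrate(
    profile: Profile,
    params: AlignParams | None = None,
    spec: DecoySpec | None = None,
    n_samples: int = 1000,
) -> GammaNull:
    """End-to-end calibration: sample null scores and fit the Gamma null."""
    if spec is None:
        spec = DecoySpec()
    scores = sample_null_scores(profile, spec, params, n_samples)
    return fit_null(scores, profile_id=profile.query_id, seed=spec.seed)
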