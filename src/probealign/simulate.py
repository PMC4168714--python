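"""Planted-homolog benchmark generator and ROC evaluation.

Builds synthetic search problems with known ground truth: mutated copies of
a family's consensus ("positives") are planted inside random structured
decoy backgrounds, reactivities are simulated with a controllable
concordance (the fraction of sites whose reactivity is drawn from the
density matching the true pairing state; 1.0 emulates ideal probing, 0.5
uninformative probing), and a truth table records the planted coordinates
for TP/FP counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import AlignmentHit
from .io import ReactivityTrack, write_reactivities
from .nullmodel import DecoySpec, _segment_from_grammar, assign_structure
from .profiles import Profile
from .reactivity import ReactivityDensityModel, default_shape_model

__all__ = [
    "PlantedBenchmark",
    "mutate_homolog",
    "build_benchmark",
    "evaluate_roc",
]

_BASES = "ACGU"
_CANONICAL = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]


@dataclass
class PlantedBenchmark:
    """Targets, reactivity tracks and the truth table of planted homologs."""

    targets: dict[str, str]
    tracks: dict[str, ReactivityTrack]
    truth: list[tuple[str, int, int, str]]  # (target_id, start, end, family_id); 1-based inclusive
    params: dict = field(default_factory=dict)

    def write(self, outdir: str | Path, prefix: str = "benchmark") -> dict[str, Path]:
        """Emit FASTA, per-target SHAPE reactivity files and a truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{prefix}.fasta"
        with open(fasta, "w") as fh:
            for tid, seq in self.targets.items():
                fh.write(f">{tid}\n")
                for k in range(0, len(seq), 60):
                    fh.write(seq[k : k + 60] + "\n")
        paths = {"fasta": fasta}
        for tid, track in self.tracks.items():
            p = outdir / f"{prefix}.{tid}.shape"
            write_reactivities(track, p)
            paths[tid] = p
        truth_path = outdir / f"{prefix}.truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("target_id\tstart\tend\tfamily_id\n")
            for tid, s, e, fam in self.truth:
                fh.write(f"{tid}\t{s}\t{e}\t{fam}\n")
        paths["truth"] = truth_path
        return paths


def mutate_homolog(
    profile: Profile,
    mutation_rate: float = 0.1,
    indel_rate: float = 0.0,
    seed: int = 0,
    compensatory: bool = False,
) -> str:
    """A mutated copy of the profile consensus.

    Substitutions hit each site i.i.d. at ``mutation_rate``; single-base
    indels at ``indel_rate`` per site.  In ``compensatory`` mode a
    substitution landing on a paired column rewrites both partners to a
    random canonical pair, preserving the consensus structure.
    """
    if not (0 <= mutation_rate <= 0.5 and 0 <= indel_rate <= 0.5):
        raise ValueError("rates must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    seq = list(profile.consensus())
    n = len(seq)

    sub_sites = np.flatnonzero(rng.random(n) < mutation_rate)
    handled: set[int] = set()
    for i in sub_sites:
        i = int(i)
        if i in handled:
            continue
        partner = profile.pair_table.get(i)
        if compensatory and partner is not None:
            a, b = _CANONICAL[rng.integers(len(_CANONICAL))]
            lo, hi = (i, partner) if i < partner else (partner, i)
            seq[lo], seq[hi] = a, b
            handled.update((i, partner))
        else:
            choices = [b for b in _BASES if b != seq[i]]
            seq[i] = choices[rng.integers(3)]
            handled.add(i)

    if indel_rate > 0:
        out: list[str] = []
        for i in range(n):
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(seq[i])
            if indel_rate / 2 <= r < indel_rate:
                out.append(_BASES[rng.integers(4)])  # insertion after i
        seq = out if out else seq
    return "".join(seq)


def _planted_reactivities(
    seq: str,
    pairedness: np.ndarray,
    concordance: float,
    model: ReactivityDensityModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reactivities drawn from the correct conditional density with the
    given probability per site, and from the wrong one otherwise."""
    n = len(seq)
    correct = rng.random(n) < concordance
    effective = np.where(correct, pairedness, 1 - pairedness)
    values = np.empty(n)
    for flag, density in ((0, model.density_paired), (1, model.density_unpaired)):
        idx = np.flatnonzero(effective == flag)
        values[idx] = density.sample(len(idx), rng)
    return values


def build_benchmark(
    profile: Profile,
    n_positives: int = 20,
    n_decoys: int = 20,
    spec: DecoySpec | None = None,
    concordance: float = 1.0,
    mutation_rate: float = 0.25,
    indel_rate: float = 0.02,
    compensatory: bool = False,
    seed: int = 0,
    model: ReactivityDensityModel | None = None,
) -> PlantedBenchmark:
    """Plant mutated homologs in decoy backgrounds with simulated probing.

    Each positive target is decoy-flank + homolog + decoy-flank; pure-decoy
    targets carry no homolog.  The planted region's pairing states come from
    the family consensus structure mapped through the homolog; flank states
    come from folding the flanks.  Truth coordinates are 1-based inclusive.
    """
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must be in [0, 1]")
    if spec is None:
        spec = DecoySpec(segment_length=max(100, 2 * profile.n))
    if model is None:
        model = default_shape_model()
    rng = np.random.default_rng(seed)

    targets: dict[str, str] = {}
    tracks: dict[str, ReactivityTrack] = {}
    truth: list[tuple[str, int, int, str]] = []

    def flank(length: int) -> str:
        return _segment_from_grammar(length, spec.gc_content, rng)

    for k in range(n_positives):
        homolog = mutate_homolog(
            profile,
            mutation_rate,
            indel_rate,
            seed=int(rng.integers(2**31 - 1)),
            compensatory=compensatory,
        )
        left = flank(spec.segment_length)
        right = flank(spec.segment_length)
        seq = left + homolog + right
        start0 = len(left)
        end0 = start0 + len(homolog)  # half-open

        # pairing states: consensus structure over the planted span (the
        # homolog inherits the family's structure), folded flanks elsewhere
        pairedness = np.ones(len(seq), dtype=np.int8)
        lp, _ = assign_structure(left)
        rp, _ = assign_structure(right)
        pairedness[:start0] = lp
        pairedness[end0:] = rp
        hom_pair = _homolog_pairedness(profile, len(homolog), mutation_rate, indel_rate)
        pairedness[start0:end0] = hom_pair

        values = _planted_reactivities(seq, pairedness, concordance, model, rng)
        tid = f"pos{k:03d}"
        targets[tid] = seq
        tracks[tid] = ReactivityTrack(values, np.ones(len(seq), dtype=bool))
        truth.append((tid, start0 + 1, end0, profile.query_id))

    for k in range(n_decoys):
        seq = flank(2 * spec.segment_length + profile.n)
        pairedness, _ = assign_structure(seq)
        values = _planted_reactivities(seq, pairedness, concordance, model, rng)
        tid = f"neg{k:03d}"
        targets[tid] = seq
        tracks[tid] = ReactivityTrack(values, np.ones(len(seq), dtype=bool))

    return PlantedBenchmark(
        targets=targets,
        tracks=tracks,
        truth=truth,
        params={
            "n_positives": n_positives,
            "n_decoys": n_decoys,
            "concordance": concordance,
            "mutation_rate": mutation_rate,
            "indel_rate": indel_rate,
            "compensatory": compensatory,
            "seed": seed,
            "gc_content": spec.gc_content,
            "segment_length": spec.segment_length,
        },
    )


def _homolog_pairedness(
    profile: Profile, homolog_length: int, mutation_rate: float, indel_rate: float
) -> np.ndarray:
    """Consensus pairedness stretched/cropped onto the homolog's length.

    With indels the column-to-position map is inexact; a uniform stretch is
    an adequate approximation for simulated probing tracks.
    """
    src = profile.pairedness
    if homolog_length == profile.n:
        return src.copy()
    idx = np.minimum(
        (np.arange(homolog_length) * profile.n // max(homolog_length, 1)),
        profile.n - 1,
    )
    return src[idx]


def evaluate_roc(
    hits: list[AlignmentHit],
    truth: list[tuple[str, int, int, str]],
    overlap_fraction: float = 0.5,
) -> tuple[int, int, list[tuple[float, float]]]:
    """TP/FP counts and rank-threshold ROC points for ranked hits.

    A hit is a true positive when it overlaps a truth interval by at least
    ``overlap_fraction`` of the shorter interval; each truth interval is
    creditable once.  Hits must arrive ranked best-first (ascending
    p-value / descending score).  ROC points are (FP count, TP count)
    cumulative down the ranking, prefixed by (0, 0).
    """
    credited: set[int] = set()
    tp = fp = 0
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for hit in hits:
        matched = False
        for t_idx, (tid, ts, te, _fam) in enumerate(truth):
            if t_idx in credited or tid != hit.target_id:
                continue
            ov = min(hit.target_end, te) - max(hit.target_start, ts) + 1
            shorter = min(hit.target_end - hit.target_start, te - ts) + 1
            if ov > 0 and ov >= overlap_fraction * shorter:
                credited.add(t_idx)
                matched = True
                break
        if matched:
            tp += 1
        else:
            fp += 1
        points.append((float(fp), float(tp)))
    return tp, fp, points


def roc_area(points: list[tuple[float, float]], n_truth: int, max_fp: int | None = None) -> float:
    """Normalized area under the rank-threshold ROC curve.

    Trapezoidal area of TP-vs-FP, normalized by (max_fp * n_truth); hits
    beyond ``max_fp`` false positives are ignored.  Returns a value in
    [0, 1]; 1.0 means every truth interval is found before any false
    positive.
    """
    if n_truth == 0:
        return 0.0
    if max_fp is None:
        max_fp = max(int(points[-1][0]), 1)
    area = 0.0
    prev_fp, prev_tp = 0.0, 0.0
    for fpc, tpc in points[1:]:
        if fpc > max_fp:
            fpc = float(max_fp)
        if fpc > prev_fp:
            area += (fpc - prev_fp) * (tpc + prev_tp) / 2.0
        prev_fp, prev_tp = fpc, tpc
        if prev_fp >= max_fp:
            break
    # extend the curve horizontally to max_fp at the final TP level
    if prev_fp < max_fp:
        area += (max_fp - prev_fp) * prev_tp
    return area / (max_fp * n_truth)
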