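"""Quantify how much structure probing helps homology detection.

Runs the same planted-homolog benchmark three ways — with fully
structure-concordant reactivities, with uninformative (coin-flip)
reactivities, and with the structural term switched off — and compares
ROC areas.  Informative probing should strictly improve the ranking of
true homologs over decoys; uninformative probing should be no better
than ignoring reactivities entirely.
"""

import numpy as np

from probealign import AlignParams, Profile, align, build_benchmark, evaluate_roc
from probealign.simulate import roc_area

SEQ = "GGCGCAAGGCAUUCGCAUGCCAAGCGCC"
SS = "<<<<<....<<<....>>>....>>>>>"
profile = Profile.from_consensus(SEQ, SS, query_id="hairpin")


def benchmark_area(concordance: float, params: AlignParams, seed: int) -> float:
    bench = build_benchmark(
        profile, n_positives=20, n_decoys=20, concordance=concordance,
        mutation_rate=0.25, seed=seed,
    )
    hits = [
        align(profile, seq, bench.tracks[tid], params, target_id=tid)
        for tid, seq in bench.targets.items()
    ]
    hits.sort(key=lambda h: -h.combined_score)
    _, _, points = evaluate_roc(hits, bench.truth)
    return roc_area(points, len(bench.truth), max_fp=20)


seeds = (11, 12, 13)
area_concordant = np.mean([benchmark_area(1.0, AlignParams(), s) for s in seeds])
area_coinflip = np.mean([benchmark_area(0.5, AlignParams(), s) for s in seeds])
area_no_struct = np.mean([benchmark_area(0.5, AlignParams(alpha=0.0), s) for s in seeds])

print(f"ROC area, concordant probing (concordance 1.0): {area_concordant:.3f}")
print(f"ROC area, uninformative probing (concordance 0.5): {area_coinflip:.3f}")
print(f"ROC area, structural term off (alpha = 0): {area_no_struct:.3f}")
print()
print("Concordant probing ranks the mutated homologs strictly better; a")
print("coin-flip reactivity track is equivalent (up to noise) to not using")
print("the probing signal at all.")
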