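# Methods

## Problem and model

`probealign` annotates candidate ncRNA homologs in sequences that carry
per-nucleotide structure-probing reactivities. The key modelling move is
asymmetry: the query family contributes only per-column *pairedness flags*
(plus sequence frequencies), while the pairing evidence for the target
comes from its reactivity track rather than from folding or covariance
alignment. This reduces structure-aware search to an O(nm) profile-to-
sequence alignment.

### Profile construction

Columns whose gap frequency is strictly greater than 0.5 (parameter
`gap_exclusion_fraction`) are excluded from the profile. Frequencies are
computed over all records with gaps counted in the gap slot; an optional
Laplace pseudocount (default 0) can be spread over A/C/G/U for very small
families. When one end of a consensus pair falls in an excluded column the
surviving end is demoted to unpaired: the per-site score needs only the
flag, and keeping a pairedness flag whose partner no longer exists would
corrupt the consistency bonus. Pseudoknot letter annotations in the
consensus structure are treated as unpaired; the scoring model consumes
only per-site flags and a nested pair table.

### Alignment scoring

The DP is semi-global (glocal): the full profile must be consumed, target
flanks are free (`M[0, j] = 0`, final score `max_j M[n, j]`). A gap of
length L costs ε₀ + L·ε_e with ε₀, ε_e ≤ 0 (defaults −4, −1). The default
substitution matrix is +2 match / −1 mismatch over {A,C,G,U}, 0 for X, and
−1 for the profile gap slot against any base; any 6×5 labeled table can be
supplied instead. These are tool defaults, deliberately simple; RIBOSUM-
style matrices can be dropped in via `--matrix`.

Reactivities are target properties: deleted profile columns consume no
reactivity, and target bases skipped by insertions are not scored. The
structural term τ is exactly 0 at undefined positions — a target with no
probing data degrades gracefully to pure sequence alignment (identical to
an α = 0 run; this reduction is asserted in the tests).

Two structural scoring functions are implemented. The *simplified* rule
scores ±1 by whether the cutoff call (unpaired iff r > r_c, the boundary
r = r_c counting as paired) agrees with the column flag. The
*protocol-specific* rule is the log-likelihood ratio
log p(r|π = s) − log p(r|π ≠ s) in natural log, with equal priors on
paired/unpaired baked in. Densities are clamped at 1e−12 before the log so
scores saturate instead of diverging. The shipped default densities —
paired ~ Exponential(mean 0.15), unpaired ~ Gamma(shape 1.5, scale 0.6;
mean 0.9) — are repo defaults shaped like published SHAPE reactivity
summaries (paired mass near 0, heavy right tail when unpaired); they are
configuration data to be re-estimated per protocol, not measured
constants. The monotonicity of the default log-ratio in r holds over the
bulk support (checked on [0, 3.5]); beyond r ≈ 4.2 the paired density
underflows the clamp floor and the saturated ratio flattens and eventually
tracks the unpaired tail — irrelevant in practice since SHAPE-normalized
reactivities rarely exceed ~4.

Traceback tie-breaking is fixed (match > delete > insert; smallest end
column on equal end scores), so alignments are deterministic. The
structure-consistency bonus (+1 per consensus pair whose two matched
target bases are canonical, X never pairing) is added to the reported
combined score *after* traceback, never inside the DP — it is a separable
re-ranking term, and the null calibration uses the same on/off setting as
the search it serves.

Multi-hit scanning is greedy: take the best alignment, mask its span
(bases to X, reactivities to undefined), realign, stop at `max_hits` or
when no positive-scoring hit remains; reported hits never overlap.

## p-value calibration

Null scores are combined scores of the profile against independent random
decoys. Each decoy segment (length max(2n, `segment_length`)) is sampled
from a stochastic context-free grammar S → xSy | xS | ε whose pair
productions emit GC/CG, AU/UA or GU/UG and whose emission probabilities
are tuned so the expected GC fraction equals the requested one exactly
(pair production probability 0.4, wobble share 0.1). Segments are folded
by canonical base-pair maximization (Nussinov-style, GU allowed, hairpin
loops ≥ 3 nt, fixed tie-breaking) and reactivities are simulated from the
conditional densities given each position's pairing state. Using
independent fixed-length segments rather than sliding windows keeps the
score sample i.i.d. for the K-S diagnostics.

Scores are fitted by maximum likelihood with four candidates — normal,
Gumbel, GEV and Gamma — and each candidate's K-S statistic is recorded.
The p-value model is always the three-parameter (location-shifted) Gamma;
the four-way comparison is a retained diagnostic, not a model selector.
The Gamma location is free in the ML fit; if the optimizer fails or
returns a location at or above the sample minimum (which would put
observed scores outside the support), the fit falls back to anchoring the
location just below the minimum (min − 1e−6·range). The free-location fit
is the default because anchoring at the sample minimum systematically
biases the shape parameter low (the parameter-recovery test quantifies
this: anchored fits of Gamma(3, 2) samples recover k ≈ 2.6). p-values are
the upper-tail probability of the combined score, clamped to [0, 1].
Default calibration size is 1,000 scores (flag-exposed); the acceptance
checks use 5,000 where the uniformity test demands resolution.

## Synthetic benchmarks

The simulator plants mutated copies of the profile consensus (per-site
substitutions at `mutation_rate`, single-base indels at `indel_rate`;
optional compensatory mode rewrites both ends of a consensus pair to a
random canonical pair, preserving structure) between stochastic-grammar
flanks, and simulates reactivities with a *concordance* knob: each site's
reactivity is drawn from the density matching its true pairing state with
that probability, and from the wrong one otherwise. Concordance 1.0
emulates ideal probing, 0.5 an uninformative signal. Planted-region
pairing states are the consensus flags (uniformly stretched when indels
change the length — an approximation adequate for simulated tracks);
flank states come from folding the flanks. Evaluation counts a hit as a
true positive when it overlaps a truth interval by ≥ 50% of the shorter
interval (configurable), each truth interval creditable once, and
summarizes rankings by trapezoidal ROC area normalized over a fixed
false-positive budget.

What the synthetic data does *not* emulate: experimental reactivity
artifacts (coverage-dependent noise, normalization batch effects, primer
drop-off), thermodynamically realistic decoy structures (base-pair
maximization over-pairs relative to free-energy folding), and true family
divergence (our mutants are i.i.d. site processes, not phylogeny).
Passing benchmarks therefore demonstrate correctness of the machinery and
the qualitative value of concordant probing signal, not field performance
on any particular protocol.

## Problem sizes and numerical choices

Oracle-equivalence checks run on profiles ≤ 6 columns × targets ≤ 8 nt,
where exhaustive enumeration of all monotone matchings is exact and
instant; 240 random instances cover both scoring modes and random
parameters. Calibration checks use the 28-nt hairpin profile with 100-nt
decoy segments: 5,000 scores for the uniformity test, 1,000-score
calibration against 2,000 fresh decoy trials for the false-positive rate.
Benchmark ROC comparisons use a 49-column synthetic family (three-stem
consensus, 15 pairs), 20 positives at 25% mutation against 20 decoys,
averaged over three pinned seeds. The DP fill and the Nussinov fill are
numba kernels; everything else is numpy/scipy.

Degenerate inputs: an empty profile or target is fatal; an all-deletion
optimum (possible only with pathological scoring) reports an empty-width
anchor; zero-variance null scores abort calibration.

## Known limitations

- Sense strand only; probing reactivities are strand-specific transcript
  measurements, so no reverse-complement search is offered.
- No local (Smith–Waterman) mode, banding, or filter acceleration.
- The reactivity-convention ambiguity across protocols (flexibility vs
  protection signals) is handled by a single `--invert-reactivity` flag
  (1 − r), not by per-protocol recalibration.
- p-values are per-family raw tail probabilities; no cross-family E-value
  or multiple-testing machinery.
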