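"""Shared fixtures: a small synthetic ncRNA family and default parameters.

All fixtures are generated programmatically with pinned seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from probealign import (
    AlignParams,
    Profile,
    StockholmAlignment,
    build_profile,
    parse_pair_table,
)

# A cloverleaf-like consensus: three stems of 7/4/4 bp with short loops.
FAMILY_SS = "<<<<<<<...<<<<.....>>>>...<<<<.....>>>>...>>>>>>>"

_CANONICAL = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]


def make_family_sequence(ss: str, seed: int) -> str:
    """A random sequence compatible with a consensus structure."""
    rng = np.random.default_rng(seed)
    table = parse_pair_table(ss)
    seq = [""] * len(ss)
    for i in range(len(ss)):
        if seq[i]:
            continue
        if i in table:
            a, b = _CANONICAL[rng.integers(len(_CANONICAL))]
            seq[i], seq[table[i]] = a, b
        else:
            seq[i] = "ACGU"[rng.integers(4)]
    return "".join(seq)


@pytest.fixture(scope="session")
def family_alignment() -> StockholmAlignment:
    """Six structure-compatible members of one synthetic family.

    Members are compensatory mutants of a common reference, so paired
    columns co-vary and the per-column majority consensus keeps every
    consensus pair canonical.
    """
    from probealign import mutate_homolog

    reference = make_family_sequence(FAMILY_SS, seed=100)
    ref_profile = Profile.from_consensus(reference, FAMILY_SS)
    records = {"reference": reference}
    for k in range(5):
        records[f"member{k}"] = mutate_homolog(
            ref_profile, mutation_rate=0.12, indel_rate=0.0,
            seed=200 + k, compensatory=True,
        )
    return StockholmAlignment(records=records, ss_cons=FAMILY_SS)


@pytest.fixture(scope="session")
def family_profile(family_alignment) -> Profile:
    return build_profile(family_alignment, query_id="family")


@pytest.fixture(scope="session")
def hairpin_profile() -> Profile:
    """A single-sequence hairpin profile (one-hot columns)."""
    seq = "GGCGCAAGGCAUUCGCAUGCCAAGCGCC"
    ss = "<<<<<....<<<....>>>....>>>>>"
    return Profile.from_consensus(seq, ss, query_id="hairpin")


@pytest.fixture()
def default_params() -> AlignParams:
    return AlignParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_profile(rng: np.random.Generator, n: int) -> Profile:
    """A random profile with Dirichlet columns and random pairedness flags."""
    freqs = rng.dirichlet(np.ones(6), size=n)
    pairedness = rng.integers(0, 2, n).astype(np.int8)
    return Profile(freqs, pairedness)


def random_target(rng: np.random.Generator, m: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, m))
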