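"""Search-profile construction from a family alignment.

The query is Q = {P, S}: per-column nucleotide/gap frequency vectors P and
per-column pairedness flags S taken from the consensus structure.  Columns
composed of a majority of gaps are excluded; the specific pairing partners
are kept separately (pair_table) only to score the post-traceback
structure-consistency bonus — the alignment DP itself consumes only the
per-site flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ALPHABET, FormatError, StockholmAlignment, parse_pair_table

__all__ = ["Profile", "build_profile"]

#: Column order of every frequency vector: A, C, G, U, X, gap.
PROFILE_SYMBOLS = ALPHABET + "-"

#: Pairedness flag convention: 0 = paired, 1 = unpaired.
PAIRED, UNPAIRED = 0, 1


@dataclass
class Profile:
    """A family search profile.

    Attributes
    ----------
    freqs : (n, 6) array
        Per-retained-column frequencies over (A, C, G, U, X, -); each row
        sums to 1.
    pairedness : (n,) int array
        0 where the source column is paired in the consensus structure,
        1 where unpaired.
    pair_table : dict[int, int]
        Symmetric partner map over retained-column indices, restricted to
        consensus pairs whose both ends survived column exclusion.
    source_column_map : (n,) int array
        Retained index -> original alignment column.
    query_id : str
        Identifier used in reports.
    """

    freqs: np.ndarray
    pairedness: np.ndarray
    pair_table: dict[int, int] = field(default_factory=dict)
    source_column_map: np.ndarray | None = None
    query_id: str = "query"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.pairedness = np.asarray(self.pairedness, dtype=np.int8)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(PROFILE_SYMBOLS):
            raise ValueError("freqs must be (n, 6)")
        if len(self.pairedness) != self.n:
            raise ValueError("pairedness length mismatch")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency vectors must sum to 1")
        for i, j in self.pair_table.items():
            if self.pair_table.get(j) != i:
                raise ValueError("pair_table not symmetric")
            if self.pairedness[i] != PAIRED or self.pairedness[j] != PAIRED:
                raise ValueError("pair_table references an unpaired column")
        if self.source_column_map is None:
            self.source_column_map = np.arange(self.n)

    @property
    def n(self) -> int:
        return self.freqs.shape[0]

    def consensus(self) -> str:
        """Per-column argmax base over {A,C,G,U} (ties broken A<C<G<U).

        Gap/X mass is ignored so the consensus is always a proper sequence.
        """
        acgu = self.freqs[:, :4]
        return "".join(ALPHABET[k] for k in acgu.argmax(axis=1))

    @classmethod
    def from_consensus(
        cls, sequence: str, ss: str = "", query_id: str = "query"
    ) -> "Profile":
        """One-hot profile from a single sequence (testing/benchmark helper)."""
        sequence = sequence.upper().replace("T", "U")
        n = len(sequence)
        freqs = np.zeros((n, 6))
        for i, b in enumerate(sequence):
            freqs[i, PROFILE_SYMBOLS.index(b if b in ALPHABET else "X")] = 1.0
        if ss:
            table = parse_pair_table(ss)
            pairedness = np.array(
                [PAIRED if i in table else UNPAIRED for i in range(n)], dtype=np.int8
            )
        else:
            table = {}
            pairedness = np.full(n, UNPAIRED, dtype=np.int8)
        return cls(freqs, pairedness, dict(table), query_id=query_id)


def build_profile(
    aln: StockholmAlignment,
    gap_exclusion_fraction: float = 0.5,
    pseudocount: float = 0.0,
    query_id: str = "query",
) -> Profile:
    """Build the search profile from a family alignment.

    A column is excluded when its gap frequency is strictly greater than
    ``gap_exclusion_fraction`` (default 0.5, i.e. a majority of gaps).
    Frequencies are computed over all records, gaps counted in the gap slot;
    an optional Laplace ``pseudocount`` is spread over A,C,G,U.  A consensus
    pair with exactly one excluded end is demoted to unpaired at the
    surviving end, so the pair table only ever references retained, paired
    columns.
    """
    if not 0.5 <= gap_exclusion_fraction <= 1.0:
        raise ValueError("gap_exclusion_fraction must be in [0.5, 1]")
    if aln.nseq == 0:
        raise FormatError("empty alignment")

    seqs = list(aln.records.values())
    ncols, nseq = aln.length, aln.nseq
    counts = np.zeros((ncols, 6))
    sym_index = {c: k for k, c in enumerate(PROFILE_SYMBOLS)}
    for seq in seqs:
        for i, c in enumerate(seq):
            counts[i, sym_index[c]] += 1
    if pseudocount:
        counts[:, :4] += pseudocount
    freqs = counts / counts.sum(axis=1, keepdims=True)

    gap_frac = counts[:, 5] / nseq
    keep = gap_frac <= gap_exclusion_fraction
    if not keep.any():
        raise FormatError("profile empty: every column exceeds the gap threshold")

    orig_pairs = parse_pair_table(aln.ss_cons)
    old_to_new = {old: new for new, old in enumerate(np.flatnonzero(keep))}

    retained = np.flatnonzero(keep)
    pairedness = np.empty(len(retained), dtype=np.int8)
    pair_table: dict[int, int] = {}
    for new, old in enumerate(retained):
        partner = orig_pairs.get(old)
        if partner is None:
            pairedness[new] = UNPAIRED
        elif partner in old_to_new:
            pairedness[new] = PAIRED
            pair_table[new] = old_to_new[partner]
        else:
            # partner column excluded: demote the surviving end to unpaired
            pairedness[new] = UNPAIRED

    return Profile(
        freqs[keep],
        pairedness,
        pair_table,
        source_column_map=retained,
        query_id=query_id,
    )
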