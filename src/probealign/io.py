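"""Readers and writers for the external file formats.

Handles Stockholm family alignments (with ``#=GC SS_cons``), FASTA targets,
SHAPE-style reactivity tracks, whitespace-delimited substitution matrices,
null-model JSON files and the tabular hits report.

Coordinate convention: 0-based half-open internally, 1-based inclusive in
every file and report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "StockholmAlignment",
    "ReactivityTrack",
    "FormatError",
    "read_stockholm",
    "write_stockholm",
    "parse_pair_table",
    "read_fasta",
    "read_reactivities",
    "read_reactivity_table",
    "write_reactivities",
    "read_subst_matrix",
    "write_hits",
    "read_hits",
]

ALPHABET = "ACGUX"  # X = any unknown nucleotide
GAP_CHARS = frozenset("-.")

#: Reactivity values at or below this threshold are treated as undefined
#: (the SHAPE interchange convention uses -999 as the sentinel).
SENTINEL_THRESHOLD = -500.0

# WUSS / dot-bracket bracket classes honoured when building pair tables.
_BRACKET_PAIRS = {"<": ">", "(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _BRACKET_PAIRS.items()}


class FormatError(ValueError):
    """Raised on malformed input files."""


def _normalize_char(c: str) -> str:
    c = c.upper().replace("T", "U")
    if c in GAP_CHARS:
        return "-"
    return c if c in ALPHABET else "X"


def normalize_sequence(seq: str, *, allow_gaps: bool = True) -> str:
    """Map a raw sequence onto the {A,C,G,U,X} alphabet (plus '-' if aligned)."""
    out = "".join(_normalize_char(c) for c in seq)
    if not allow_gaps and "-" in out:
        raise FormatError("gap character in an ungapped sequence")
    return out


@dataclass
class StockholmAlignment:
    """A family alignment plus its consensus secondary structure.

    ``records`` maps sequence id to the aligned sequence over {A,C,G,U,X,-},
    in input order.  ``ss_cons`` is the consensus structure string
    (WUSS/dot-bracket) of the same length.
    """

    records: dict[str, str]
    ss_cons: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise FormatError("ragged alignment: sequences differ in length")
        if self.records and len(self.ss_cons) != next(iter(lengths)):
            raise FormatError(
                f"SS_cons length {len(self.ss_cons)} does not match "
                f"alignment length {next(iter(lengths))}"
            )

    @property
    def length(self) -> int:
        return len(self.ss_cons)

    @property
    def nseq(self) -> int:
        return len(self.records)


@dataclass
class ReactivityTrack:
    """Per-nucleotide probing reactivities for one target sequence.

    Undefined positions carry ``defined_mask[i] == False``; their numeric
    slot is NaN and is never consumed by scoring.
    """

    values: np.ndarray
    defined_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.values.shape != self.defined_mask.shape:
            raise FormatError("reactivity values/mask length mismatch")
        # undefined slots never hold a fake numeric value
        self.values = np.where(self.defined_mask, self.values, np.nan)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def undefined(cls, length: int) -> "ReactivityTrack":
        return cls(np.full(length, np.nan), np.zeros(length, dtype=bool))

    def inverted(self) -> "ReactivityTrack":
        """Flip the reactivity convention (1 - r on defined positions).

        Some protocols report protection rather than flexibility; this maps
        one convention onto the other for the defined positions.
        """
        vals = np.where(self.defined_mask, 1.0 - self.values, np.nan)
        return ReactivityTrack(vals, self.defined_mask.copy())


def read_stockholm(path: str | Path) -> StockholmAlignment:
    """Read a Stockholm alignment with a ``#=GC SS_cons`` line.

    Sequences are normalized (T->U, unknown->X, './-'->'-'); record order is
    preserved.  A missing consensus-structure line or a ragged alignment is
    fatal.
    """
    path = Path(path)
    records: dict[str, list[str]] = {}
    order: list[str] = []
    ss_parts: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("//"):
                continue
            if line.startswith("#"):
                parts = line.split()
                if len(parts) >= 3 and parts[0] == "#=GC" and parts[1] == "SS_cons":
                    ss_parts.append(parts[2])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: unparseable alignment line: {line!r}")
            name, chunk = parts
            if name not in records:
                records[name] = []
                order.append(name)
            records[name].append(chunk)
    if not records:
        raise FormatError(f"{path}: no sequences found")
    if not ss_parts:
        raise FormatError(f"{path}: missing '#=GC SS_cons' consensus structure line")
    seqs = {name: normalize_sequence("".join(records[name])) for name in order}
    return StockholmAlignment(records=seqs, ss_cons="".join(ss_parts))


def write_stockholm(aln: StockholmAlignment, path: str | Path) -> None:
    """Write a minimal single-block Stockholm file (fixture/round-trip writer)."""
    width = max([len(n) for n in aln.records] + [len("#=GC SS_cons")]) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, seq in aln.records.items():
            fh.write(f"{name:<{width}}{seq}\n")
        fh.write(f"{'#=GC SS_cons':<{width}}{aln.ss_cons}\n")
        fh.write("//\n")


def parse_pair_table(ss_cons: str) -> dict[int, int]:
    """Pair table of a consensus structure string, 0-based symmetric map.

    All four WUSS bracket classes ``<> () [] {}`` are honoured and may nest
    or interleave across classes; pseudoknot letter annotations (Aa, Bb, ...)
    are treated as unpaired, as are all other characters.  Unbalanced
    brackets are fatal.
    """
    stacks: dict[str, list[int]] = {k: [] for k in _BRACKET_PAIRS}
    pairs: dict[int, int] = {}
    for i, c in enumerate(ss_cons):
        if c in _BRACKET_PAIRS:
            stacks[c].append(i)
        elif c in _CLOSERS:
            opener = _CLOSERS[c]
            if not stacks[opener]:
                raise FormatError(
                    f"unbalanced structure string: unmatched '{c}' at column {i + 1}"
                )
            j = stacks[opener].pop()
            pairs[i] = j
            pairs[j] = i
    for opener, stack in stacks.items():
        if stack:
            raise FormatError(
                f"unbalanced structure string: {len(stack)} unmatched '{opener}'"
            )
    return pairs


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read target sequences; normalized to {A,C,G,U,X}, order preserved."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = normalize_sequence(str(rec.seq), allow_gaps=False)
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def read_reactivities(path: str | Path, target_length: int) -> ReactivityTrack:
    """Read a two-column SHAPE-dialect reactivity file for one target.

    Lines are ``<position> <reactivity>`` with 1-based positions.  The
    sentinel -999 (any value below the sentinel threshold) and positions
    absent from the file are undefined.
    """
    path = Path(path)
    values = np.full(target_length, np.nan)
    mask = np.zeros(target_length, dtype=bool)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'position reactivity'")
            try:
                pos = int(parts[0])
                val = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if not 1 <= pos <= target_length:
                raise FormatError(
                    f"{path}:{lineno}: position {pos} outside [1, {target_length}]"
                )
            if val <= SENTINEL_THRESHOLD:
                continue
            values[pos - 1] = val
            mask[pos - 1] = True
    return ReactivityTrack(values, mask)


def read_reactivity_table(path: str | Path, target_lengths: dict[str, int]) -> dict[str, ReactivityTrack]:
    """Read the multi-target dialect: tab/space-delimited ``id position reactivity``."""
    path = Path(path)
    tracks = {
        tid: (np.full(n, np.nan), np.zeros(n, dtype=bool))
        for tid, n in target_lengths.items()
    }
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 'target_id position reactivity'")
            tid = parts[0]
            if tid not in tracks:
                raise FormatError(f"{path}:{lineno}: unknown target id {tid!r}")
            try:
                pos = int(parts[1])
                val = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            n = target_lengths[tid]
            if not 1 <= pos <= n:
                raise FormatError(f"{path}:{lineno}: position {pos} outside [1, {n}]")
            if val <= SENTINEL_THRESHOLD:
                continue
            tracks[tid][0][pos - 1] = val
            tracks[tid][1][pos - 1] = True
    return {tid: ReactivityTrack(v, m) for tid, (v, m) in tracks.items()}


def write_reactivities(track: ReactivityTrack, path: str | Path) -> None:
    """Write the two-column SHAPE dialect; undefined positions get -999."""
    with open(path, "w") as fh:
        for i in range(len(track)):
            val = track.values[i] if track.defined_mask[i] else -999.0
            fh.write(f"{i + 1}\t{val:.6g}\n")


def read_subst_matrix(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a whitespace-delimited labeled substitution table m(x, y).

    Rows are profile symbols (A C G U X -), columns target bases (A C G U X).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [l.split() for l in fh if l.strip() and not l.startswith("#")]
    header = [c.upper() for c in lines[0]]
    table: dict[tuple[str, str], float] = {}
    for row in lines[1:]:
        x = row[0].upper()
        for y, cell in zip(header, row[1:]):
            table[(x, y)] = float(cell)
    expected = {(x, y) for x in ALPHABET + "-" for y in ALPHABET}
    missing = expected - set(table)
    if missing:
        raise FormatError(f"{path}: substitution table missing entries, e.g. {sorted(missing)[:3]}")
    return table


_HITS_COLUMNS = [
    "query_id",
    "target_id",
    "target_start",
    "target_end",
    "dp_score",
    "consistency_score",
    "combined_score",
    "p_value",
]


def write_hits(hits: Iterable, path: str | Path) -> None:
    """Write the tab-delimited hits report.

    One hit per line with a header row; 1-based inclusive target coordinates;
    sorted by ascending p-value, ties broken by descending combined score.
    """
    rows = sorted(
        hits,
        key=lambda h: (
            h.p_value if h.p_value is not None else float("inf"),
            -h.combined_score,
        ),
    )
    with open(path, "w") as fh:
        fh.write("\t".join(_HITS_COLUMNS) + "\n")
        for h in rows:
            pv = "NA" if h.p_value is None else f"{h.p_value:.6g}"
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.target_start}\t{h.target_end}\t"
                f"{h.dp_score:.6g}\t{h.consistency_score:.6g}\t"
                f"{h.combined_score:.6g}\t{pv}\n"
            )


def read_hits(path: str | Path) -> list[dict]:
    """Read back a hits report as a list of dicts (round-trip support)."""
    out: list[dict] = []
    with open(path) as fh:
        header = fh.readline().split()
        if header != _HITS_COLUMNS:
            raise FormatError(f"{path}: unexpected hits header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rec = dict(zip(header, parts))
            rec["target_start"] = int(rec["target_start"])
            rec["target_end"] = int(rec["target_end"])
            for k in ("dp_score", "consistency_score", "combined_score"):
                rec[k] = float(rec[k])
            rec["p_value"] = None if rec["p_value"] == "NA" else float(rec["p_value"])
            out.append(rec)
    return out


def write_null_json(null, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(null.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_null_json(path: str | Path):
    from .nullmodel import GammaNull

    with open(path) as fh:
        return GammaNull.from_dict(json.load(fh))
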