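"""Degenerate antisense (paratope) pattern generation and screening plumbing.

An epitope maps position-wise, through the genetic-code antisense relation,
to a *degenerate pattern*: an ordered list of residue sets, one per epitope
position (position order is preserved; any reading-direction reversal happens
inside the per-codon mapping).  The pattern compactly represents every
concrete antisense peptide — candidate paratopes — as its Cartesian product.
Fixed-length windows of the pattern (pentapeptides by default) are enumerated,
exported as FASTA for an external protein–protein BLAST screen against
antibody sequences, and re-ranked by the number of distinct antibody subjects
hit.  Selected window motifs are finally joined into one antisense peptide.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    AMINO_ACIDS,
    AlphabetError,
    AntisenseMap,
    Direction,
    build_antisense_map,
    group_label,
)

__all__ = [
    "EPO_P2_EPITOPE",
    "EPO_P2_ANTISENSE",
    "Epitope",
    "DegeneratePattern",
    "PatternWindow",
    "MotifChoice",
    "BlastHit",
    "antisense_pattern",
    "pattern_cardinality",
    "enumerate_peptides",
    "pattern_windows",
    "join_motifs",
    "validate_antisense_pair",
    "PairReport",
    "export_candidates_fasta",
    "parse_blast_tabular",
    "rank_windows_by_hits",
    "candidate_id",
    "decode_candidate_id",
]


# The worked example: the C-terminal receptor-binding epitope of human
# erythropoietin (EPO-P2) and the antisense peptide designed against it.
EPO_P2_EPITOPE = "LKLYTGEACRTGDR"
EPO_P2_ANTISENSE = "DFDIWPLRTAWPLS"


@dataclass(frozen=True)
class Epitope:
    """A target epitope: residue string plus optional parent coordinates
    (1-based inclusive, as in '152–166 aa')."""

    sequence: str
    label: str = ""
    parent_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("epitope sequence must be non-empty")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS:
                raise AlphabetError(
                    f"non-standard residue {aa!r} at epitope position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DegeneratePattern:
    """Position-wise residue sets representing all antisense peptides.

    ``symbols`` is the compact display form: the Greek group label where the
    genetic code defines one for the sense residue's antisense set, else the
    single antisense residue letter (e.g. αFαεδPLRTζδPLζ).
    """

    positions: tuple[frozenset[str], ...]
    symbols: tuple[str, ...]
    direction: Direction

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("degenerate pattern must have at least one position")
        if any(not s for s in self.positions):
            raise ValueError("every pattern position set must be non-empty")
        if len(self.symbols) != len(self.positions):
            raise ValueError("one display symbol per pattern position required")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def display(self) -> str:
        return "".join(self.symbols)


@dataclass(frozen=True)
class PatternWindow:
    """A contiguous slice of a degenerate pattern, at a 0-based offset."""

    pattern: DegeneratePattern
    offset: int

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("window offset must be >= 0")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def display(self) -> str:
        return self.pattern.display


@dataclass(frozen=True)
class MotifChoice:
    """A concrete peptide drawn position-wise from one pattern window."""

    window: PatternWindow
    peptide: str

    def __post_init__(self) -> None:
        if len(self.peptide) != len(self.window):
            raise ValueError(
                f"peptide length {len(self.peptide)} does not match window "
                f"length {len(self.window)}"
            )
        for i, aa in enumerate(self.peptide):
            if aa not in self.window.pattern.positions[i]:
                raise ValueError(
                    f"residue {aa!r} at motif position {i + 1} is not in the "
                    f"window's position set"
                )


def antisense_pattern(epitope: Epitope, direction: Direction) -> DegeneratePattern:
    """Degenerate antisense pattern of an epitope: position i's set is the
    antisense residue set of epitope[i].  Epitope position order is kept."""
    amap = build_antisense_map(direction)
    positions = tuple(amap[aa] for aa in epitope.sequence)
    symbols = tuple(group_label(amap, aa) for aa in epitope.sequence)
    return DegeneratePattern(positions=positions, symbols=symbols, direction=direction)


def pattern_cardinality(p: DegeneratePattern | PatternWindow) -> int:
    """Number of concrete peptides the pattern represents (product of set sizes)."""
    positions = p.pattern.positions if isinstance(p, PatternWindow) else p.positions
    card = 1
    for s in positions:
        card *= len(s)
    return card


def enumerate_peptides(
    p: DegeneratePattern | PatternWindow, limit: int | None = None
) -> list[str]:
    """All concrete peptides of a pattern, in lexicographic product order
    (each position's set alphabetically sorted).

    ``limit`` guards against combinatorial blow-up: enumeration refuses when
    the cardinality exceeds it.
    """
    card = pattern_cardinality(p)
    if limit is not None and card > limit:
        raise ValueError(
            f"pattern cardinality {card} exceeds limit {limit}; "
            "enumerate windows separately or stream the product"
        )
    positions = p.pattern.positions if isinstance(p, PatternWindow) else p.positions
    pools = [sorted(s) for s in positions]
    return ["".join(t) for t in itertools.product(*pools)]


def pattern_windows(p: DegeneratePattern, k: int = 5) -> list[PatternWindow]:
    """All contiguous length-``k`` windows of the pattern, left to right."""
    if k < 1:
        raise ValueError(f"window length must be >= 1, got {k}")
    if k > len(p):
        raise ValueError(
            f"window length {k} exceeds pattern length {len(p)}"
        )
    out = []
    for off in range(len(p) - k + 1):
        sub = DegeneratePattern(
            positions=p.positions[off : off + k],
            symbols=p.symbols[off : off + k],
            direction=p.direction,
        )
        out.append(PatternWindow(pattern=sub, offset=off))
    return out


def join_motifs(choices: Sequence[MotifChoice]) -> str:
    """Concatenate motif choices whose windows tile the pattern contiguously.

    Windows must cover consecutive offsets without gaps or overlaps; the
    result is itself a member of the full pattern.
    """
    if not choices:
        raise ValueError("no motif choices to join")
    ordered = sorted(choices, key=lambda c: c.window.offset)
    expected = ordered[0].window.offset
    for c in ordered:
        if c.window.offset != expected:
            kind = "overlap" if c.window.offset < expected else "gap"
            raise ValueError(
                f"{kind} between motif windows at offset {c.window.offset} "
                f"(expected offset {expected})"
            )
        expected = c.window.offset + len(c.window)
    return "".join(c.peptide for c in ordered)


@dataclass(frozen=True)
class PairReport:
    """Outcome of a position-wise sense–antisense validation."""

    ok: bool
    failures: tuple[tuple[int, str, str, frozenset[str]], ...]
    # each failure: (1-based position, sense residue, candidate residue, allowed set)

    def __bool__(self) -> bool:
        return self.ok


def validate_antisense_pair(
    sense: str, candidate: str, direction: Direction
) -> PairReport:
    """Check that ``candidate`` is a position-wise antisense peptide of
    ``sense`` under the given direction; failures list offending positions."""
    if len(sense) != len(candidate):
        raise ValueError(
            f"length mismatch: sense {len(sense)} vs candidate {len(candidate)}"
        )
    amap = build_antisense_map(direction)
    failures = []
    for i, (s, c) in enumerate(zip(sense, candidate), start=1):
        allowed = amap[s]
        if c not in allowed:
            failures.append((i, s, c, allowed))
    return PairReport(ok=not failures, failures=tuple(failures))


def candidate_id(offset: int, index: int) -> str:
    """Deterministic FASTA ID for an enumerated window candidate."""
    return f"anti|off{offset}|i{index:05d}"


_ID_RE = re.compile(r"off(\d+)\|i(\d+)")


def decode_candidate_id(qseqid: str) -> tuple[int, int]:
    """Recover (window offset, enumeration index) from a candidate ID."""
    m = _ID_RE.search(qseqid)
    if m is None:
        raise ValueError(f"query id {qseqid!r} does not encode a window offset")
    return int(m.group(1)), int(m.group(2))


def export_candidates_fasta(
    peptides: Sequence[str], path: str | Path, offset: int = 0
) -> None:
    """Write enumerated candidate peptides as FASTA with IDs encoding the
    window offset and enumeration index (stable across runs)."""
    if not peptides:
        raise ValueError("no candidate peptides to export")
    records = [
        SeqRecord(Seq(pep), id=candidate_id(offset, i), description="")
        for i, pep in enumerate(peptides)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class BlastHit:
    """One hit line of a 12-column (outfmt-6-style) BLAST tabular file."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def parse_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column BLAST tabular file; malformed lines raise with the
    offending line number."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hits.append(
                    BlastHit(
                        qseqid=cols[0],
                        sseqid=cols[1],
                        pident=float(cols[2]),
                        length=int(cols[3]),
                        mismatch=int(cols[4]),
                        gapopen=int(cols[5]),
                        qstart=int(cols[6]),
                        qend=int(cols[7]),
                        sstart=int(cols[8]),
                        send=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return hits


def rank_windows_by_hits(
    windows: Sequence[PatternWindow], hits: Iterable[BlastHit]
) -> list[tuple[PatternWindow, int]]:
    """Rank pattern windows by the number of *distinct* BLAST subjects their
    candidates hit; ties broken toward the leftmost offset."""
    subjects: dict[int, set[str]] = {w.offset: set() for w in windows}
    for hit in hits:
        offset, _ = decode_candidate_id(hit.qseqid)
        if offset in subjects:
            subjects[offset].add(hit.sseqid)
    ranked = sorted(windows, key=lambda w: (-len(subjects[w.offset]), w.offset))
    return [(w, len(subjects[w.offset])) for w in ranked]
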