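"""Sense→antisense amino-acid mapping derived from the standard genetic code.

A peptide's mRNA can be complemented base-wise (U↔A, C↔G) and read in either
transcription direction.  Translating the complemented codons gives, for each
sense amino acid, a small set of "antisense" residues — the residues a
complementary-strand peptide would carry at that position.  Reading the
complemented triplet in place (3'→5') yields 27 sense–antisense pairs over the
20 amino acids; reading it backwards (5'→3', i.e. reverse complement) yields
52.  Both maps are derived here computationally from translation table 1,
never hard-coded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Data import CodonTable

__all__ = [
    "RNA_BASES",
    "AMINO_ACIDS",
    "Direction",
    "AlphabetError",
    "AntisenseMap",
    "complement_base",
    "antisense_codon",
    "antisense_residues",
    "build_antisense_map",
    "pair_count",
    "group_label",
    "write_map_tsv",
]

RNA_BASES = frozenset("UCAG")
#: The 20 standard amino acids, one-letter code.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = {"U": "A", "A": "U", "C": "G", "G": "C"}


class AlphabetError(ValueError):
    """A character outside the expected residue or base alphabet."""


class Direction(enum.Enum):
    """Reading direction of the complementary mRNA strand.

    ``THREE_TO_FIVE`` complements each codon in place (1st-2nd-3rd base order
    kept); ``FIVE_TO_THREE`` complements and reads the triplet backwards
    (3rd-2nd-1st), i.e. the reverse complement.
    """

    THREE_TO_FIVE = "3'->5'"
    FIVE_TO_THREE = "5'->3'"


# Greek group labels conventionally attached to the multi-residue antisense
# sets; singleton sets carry no label.  Keyed by the *sense* amino acid since
# two sense residues may share one antisense set under different labels.
_GROUP_LABELS: dict[Direction, dict[str, str]] = {
    Direction.THREE_TO_FIVE: {
        "L": "α", "V": "β", "S": "γ", "T": "δ", "Y": "ε", "R": "ζ",
    },
    Direction.FIVE_TO_THREE: {
        "F": "η", "L": "θ", "I": "ι", "V": "κ", "S": "λ", "P": "μ",
        "T": "ν", "A": "ξ", "Y": "ο", "H": "π", "N": "ρ", "K": "ς",
        "D": "σ", "E": "τ", "C": "υ", "R": "φ", "G": "χ",
    },
}


def complement_base(base: str) -> str:
    """Watson–Crick complement of one RNA base (U↔A, C↔G). Involutive."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(
            f"not an RNA base: {base!r} (expected one of U, C, A, G)"
        ) from None


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in RNA_BASES for b in codon):
        raise AlphabetError(
            f"not a valid RNA codon: {codon!r} (three bases over U/C/A/G)"
        )


def antisense_codon(codon: str, direction: Direction) -> str:
    """Complement a codon base-wise; for 5'→3' also reverse the triple."""
    _check_codon(codon)
    comp = "".join(_COMPLEMENT[b] for b in codon)
    if direction is Direction.FIVE_TO_THREE:
        comp = comp[::-1]
    return comp


@lru_cache(maxsize=1)
def _standard_table() -> tuple[Mapping[str, str], frozenset[str]]:
    """(codon→amino-acid for the 61 coding codons, the 3 stop codons)."""
    table = CodonTable.unambiguous_rna_by_id[1]
    return dict(table.forward_table), frozenset(table.stop_codons)


def codons_for(aa: str) -> tuple[str, ...]:
    """All standard-code codons of one amino acid, in alphabetical order."""
    if aa not in AMINO_ACIDS:
        raise AlphabetError(f"unknown amino acid: {aa!r}")
    forward, _ = _standard_table()
    return tuple(sorted(c for c, a in forward.items() if a == aa))


def antisense_residues(aa: str, direction: Direction) -> frozenset[str]:
    """Antisense amino acids of ``aa`` for one transcription direction.

    Union of the translations of the antisense codons over every codon of
    ``aa``; antisense triples that are stop codons are discarded.  Never
    empty for the standard code.
    """
    forward, stops = _standard_table()
    out = set()
    for codon in codons_for(aa):
        anti = antisense_codon(codon, direction)
        if anti in stops:
            continue
        out.add(forward[anti])
    return frozenset(out)


@dataclass(frozen=True)
class AntisenseMap:
    """Complete sense→antisense residue map for one direction.

    ``pairs`` maps each of the 20 amino acids to its (non-empty) antisense
    set; ``group_labels`` carries the conventional Greek symbol of a sense
    residue's antisense group where one exists.
    """

    direction: Direction
    pairs: Mapping[str, frozenset[str]]
    group_labels: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.pairs) != AMINO_ACIDS:
            raise ValueError("antisense map must cover exactly the 20 amino acids")
        if any(not s for s in self.pairs.values()):
            raise ValueError("every antisense set must be non-empty")

    def __getitem__(self, aa: str) -> frozenset[str]:
        try:
            return self.pairs[aa]
        except KeyError:
            raise AlphabetError(f"unknown amino acid: {aa!r}") from None


@lru_cache(maxsize=2)
def build_antisense_map(direction: Direction) -> AntisenseMap:
    """Derive the full antisense map for ``direction`` from the codon table."""
    pairs = {aa: antisense_residues(aa, direction) for aa in sorted(AMINO_ACIDS)}
    labels = dict(_GROUP_LABELS[direction])
    return AntisenseMap(direction=direction, pairs=pairs, group_labels=labels)


def pair_count(amap: AntisenseMap) -> int:
    """Total number of sense–antisense pairs: sum of antisense-set sizes."""
    return sum(len(s) for s in amap.pairs.values())


def group_label(amap: AntisenseMap, aa: str) -> str:
    """Display symbol of ``aa``'s antisense set: Greek group label where the
    set has one, else the single antisense residue letter."""
    residues = amap[aa]
    label = amap.group_labels.get(aa)
    if label is not None:
        return label
    if len(residues) == 1:
        return next(iter(residues))
    return "".join(sorted(residues))  # unlabeled multi-set: spelled out


def write_map_tsv(amap: AntisenseMap, path: str | Path) -> None:
    """Serialize the map as TSV (residue, direction, antisense residues, label)."""
    lines = ["# amino_acid\tdirection\tantisense\tlabel"]
    for aa in sorted(amap.pairs):
        anti = ",".join(sorted(amap.pairs[aa]))
        label = amap.group_labels.get(aa, "")
        lines.append(f"{aa}\t{amap.direction.value}\t{anti}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")
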