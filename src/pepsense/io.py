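"""Sequence and tabular I/O, run configuration, and fixture generation.

File conventions: FASTA for sequences (via Biopython), TSV with ``#``-prefixed
header/metadata lines for derived tables, and CSV with a ``#`` key-value
metadata block for titrations — all plain text so diffs stay reviewable.
Residue coordinates in user-facing output are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import binding_models, epitope_scan, genetic_code, paratope_design
from .binding_models import BindingParams, SpectraMatrix, TitrationSeries
from .genetic_code import AMINO_ACIDS, AlphabetError, Direction

__all__ = [
    "SequenceRecord",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_titration_csv",
    "write_titration_csv",
    "read_spectra_csv",
    "write_spectra_csv",
    "load_config",
    "make_fixtures",
]

#: Ambiguity codes admitted when strict validation is off.
EXTENDED_RESIDUES = frozenset("XBZ")


@dataclass(frozen=True)
class SequenceRecord:
    """A validated protein sequence record."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")


def _validate_residues(rec_id: str, residues: str, strict: bool) -> None:
    allowed = AMINO_ACIDS if strict else AMINO_ACIDS | EXTENDED_RESIDUES
    for i, aa in enumerate(residues, start=1):
        if aa not in allowed:
            raise AlphabetError(
                f"record {rec_id!r}: illegal residue {aa!r} at position {i}"
            )


def read_fasta(path: str | Path, strict: bool = True) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records, preserving order.

    Wrapped sequence lines are joined; under strict validation only the 20
    standard residues are admitted (X/B/Z additionally when ``strict`` is
    off, with scale lookups on them failing loudly downstream).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        _validate_residues(rec.id, residues, strict)
        records.append(
            SequenceRecord(id=rec.id, description=rec.description, residues=residues)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA; round-trips with :func:`read_fasta`."""
    if not records:
        raise ValueError("no records to write")
    out = [
        SeqRecord(Seq(r.residues), id=r.id,
                  description=r.description if r.description != r.id else "")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    """Titration CSV: ``#`` key-value metadata block, then titrant_uM,signal."""
    lines = [f"# fixed_uM = {series.fixed_total:.10g}"]
    for key, val in sorted(series.meta.items()):
        lines.append(f"# {key} = {val}")
    lines.append("titrant_uM,signal")
    for t, s in zip(series.titrant_totals, series.signal):
        lines.append(f"{t:.10g},{s:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_titration_csv(path: str | Path) -> TitrationSeries:
    """Read a titration CSV written by :func:`write_titration_csv`."""
    meta: dict[str, str] = {}
    titrants, signals = [], []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            header_seen = True  # column header line
            continue
        try:
            t, s = line.split(",")
            titrants.append(float(t))
            signals.append(float(s))
        except ValueError:
            raise ValueError(f"{path}, line {lineno}: malformed data row {line!r}")
    if "fixed_uM" not in meta:
        raise ValueError(f"{path}: missing '# fixed_uM = ...' metadata line")
    fixed = float(meta.pop("fixed_uM"))
    return TitrationSeries(
        fixed_total=fixed,
        titrant_totals=np.array(titrants),
        signal=np.array(signals),
        meta=meta,
    )


def write_spectra_csv(m: SpectraMatrix, path: str | Path) -> None:
    """Spectra matrix as CSV with the wavelength grid as the header row."""
    lines = ["wavelength_nm," + ",".join(f"{w:.10g}" for w in m.wavelengths)]
    for i, row in enumerate(m.spectra):
        lines.append(f"point{i}," + ",".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectra_csv(path: str | Path) -> SpectraMatrix:
    """Read a spectra CSV written by :func:`write_spectra_csv`."""
    rows = Path(path).read_text().splitlines()
    wavelengths = np.array([float(v) for v in rows[0].split(",")[1:]])
    spectra = np.array(
        [[float(v) for v in r.split(",")[1:]] for r in rows[1:] if r.strip()]
    )
    return SpectraMatrix(wavelengths=wavelengths, spectra=spectra)


@dataclass
class RunConfig:
    """Validated run parameters shared by the CLI subcommands."""

    scale: str = "eiip"
    window: int = 6
    direction: str = "3to5"
    k: int = 5
    peaks: int = 5
    mean_center: bool = True
    fit_mode: str = "fluorescence"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in epitope_scan.SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.window < 1 or self.k < 1 or self.peaks < 1:
            raise ValueError("window, k and peaks must be >= 1")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
        if self.fit_mode not in ("fluorescence", "mst"):
            raise ValueError("fit_mode must be 'fluorescence' or 'mst'")


DIRECTIONS = {
    "3to5": Direction.THREE_TO_FIVE,
    "5to3": Direction.FIVE_TO_THREE,
}


def load_config(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse a ``command.key = value`` configuration file into per-command
    sections (flat ``key = value`` entries land in the '' section, applying
    to every command).  CLI flags always win over file values."""
    sections: dict[str, dict[str, str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}, line {lineno}: expected key = value")
        key, _, val = line.partition("=")
        key = key.strip()
        cmd, _, opt = key.rpartition(".")
        sections.setdefault(cmd, {})[opt] = val.strip()
    return sections


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

#: Distinct-antibody hit counts per pentapeptide window of the worked example
#: (offsets 0..9), used to build the mock homology-screen file.
_WINDOW_HIT_COUNTS = (20, 0, 0, 0, 0, 2, 0, 4, 6, 12)


def _mock_blast_lines(seed: int) -> list[str]:
    """Deterministic 12-column tabular hit file realising the per-window
    distinct-subject counts of the worked example."""
    rng = np.random.default_rng(seed)
    lines = []
    for offset, count in enumerate(_WINDOW_HIT_COUNTS):
        for j in range(count):
            qseqid = paratope_design.candidate_id(offset, 0)
            sseqid = f"AB{offset:02d}_{j:02d}"
            sstart = int(rng.integers(1, 90))
            pident = float(rng.choice([80.0, 100.0]))
            lines.append(
                "\t".join(
                    [
                        qseqid, sseqid, f"{pident:.1f}", "5", "0", "0",
                        "1", "5", str(sstart), str(sstart + 4),
                        "0.001", "20.0",
                    ]
                )
            )
    return lines


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a deterministic fixture bundle (same seed → byte-identical).

    Contents: the two packaged residue scales as TSV, both derived antisense
    maps as TSV, the worked-example epitope/antisense FASTA, a mock homology
    hit file realising the worked example's per-window counts, and simulated
    fluorescence/MST titrations at several K_d values.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # residue scales
    p = out / "residue_scales.tsv"
    lines = ["# amino_acid\thopp_woods\teiip_Ry"]
    for aa in sorted(AMINO_ACIDS):
        lines.append(
            f"{aa}\t{epitope_scan.HOPP_WOODS[aa]:.4g}\t{epitope_scan.EIIP[aa]:.4f}"
        )
    p.write_text("\n".join(lines) + "\n")
    paths["scales"] = p

    # antisense maps
    for tag, direction in DIRECTIONS.items():
        p = out / f"antisense_map_{tag}.tsv"
        genetic_code.write_map_tsv(genetic_code.build_antisense_map(direction), p)
        paths[f"map_{tag}"] = p

    # worked-example sequences
    p = out / "epitope_pair.fasta"
    write_fasta(
        [
            SequenceRecord("EPO-P2", "EPO-P2 epitope",
                           paratope_design.EPO_P2_EPITOPE),
            SequenceRecord("EPO-P2-antisense", "EPO-P2 antisense paratope",
                           paratope_design.EPO_P2_ANTISENSE),
        ],
        p,
    )
    paths["epitope_fasta"] = p

    # mock homology screen hits
    p = out / "mock_blast_hits.tsv"
    p.write_text("\n".join(_mock_blast_lines(seed)) + "\n")
    paths["blast_hits"] = p

    # simulated titrations (µM; the titration design of the worked example)
    titrants = np.geomspace(1.2, 75.0, 12)
    for i, kd in enumerate((100.0, 850.0, 2000.0)):
        truth = BindingParams(kd=kd, q_free=1.0, q_complex=3.0)
        series = binding_models.simulate_titration(
            truth, fixed_total=2.5, titrant_totals=titrants,
            noise_sd=0.02, seed=seed + i, mode="fluorescence",
            meta={"mode": "fluorescence", "true_kd_uM": f"{kd:g}",
                  "temperature_C": "25", "pH": "7.4"},
        )
        p = out / f"titration_fluor_kd{kd:g}.csv"
        write_titration_csv(series, p)
        paths[f"titration_fluor_kd{kd:g}"] = p

    mst_titrants = np.geomspace(0.305, 10000.0, 16)
    truth = BindingParams(kd=816.0, q_free=800.0, q_complex=860.0)
    series = binding_models.simulate_titration(
        truth, fixed_total=10.0, titrant_totals=mst_titrants,
        noise_sd=0.5, seed=seed + 100, mode="mst",
        meta={"mode": "mst", "true_kd_uM": "816",
              "temperature_C": "25", "pH": "7.4"},
    )
    p = out / "titration_mst_kd816.csv"
    write_titration_csv(series, p)
    paths["titration_mst_kd816"] = p

    return paths
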