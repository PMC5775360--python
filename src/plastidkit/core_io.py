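"""Readers/writers for the formats the pipeline touches, plus tabular reports.

Internal coordinates are 0-based half-open throughout the package; anything
written to a report is converted to 1-based inclusive (GenBank convention)
at the point of writing. Gap characters ('-') are legal only in alignments;
'.' is rejected everywhere so there is exactly one gap dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._seq import ALIGN_ALPHABET, GENOME_ALPHABET, encode

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA")


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending record."""


@dataclass
class SeqRecord:
    """A DNA sequence with an identifier.

    ``circular`` marks whole plastomes; alignment rows and region slices are
    linear. The sequence is upper-case over {A,C,G,T,N} ('-' additionally
    allowed when ``aligned=True`` at validation time).
    """

    id: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self, aligned: bool = False) -> "SeqRecord":
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        alphabet = ALIGN_ALPHABET if aligned else GENOME_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ParseError(
                f"record {self.id!r}: illegal character {self.seq[pos]!r} "
                f"at position {pos + 1}"
            )
        return self


@dataclass
class GeneFeature:
    """A gene as an ordered list of exon intervals on the canonical genome.

    parts: list of (start, end, strand) with 0-based half-open coordinates,
    ordered along transcription. ``intron_count`` is len(parts) - 1.
    For genes crossing the circular origin, intervals may extend past the
    genome length (unwrapped); positions are interpreted modulo the length.
    """

    name: str
    kind: str
    parts: list[tuple[int, int, str]]

    @property
    def intron_count(self) -> int:
        return len(self.parts) - 1

    @property
    def span(self) -> tuple[int, int]:
        """Overall extent (first part start, last part end), introns included."""
        return min(p[0] for p in self.parts), max(p[1] for p in self.parts)

    @property
    def strand(self) -> str:
        return self.parts[0][2]


@dataclass
class AlignmentMatrix:
    """A multiple sequence alignment held as an (n_rows, n_cols) uint8 matrix."""

    ids: list[str]
    matrix: np.ndarray  # uint8 ASCII codes, shape (n, L)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids/matrix row count mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ParseError("duplicate ids in alignment")
        if self.matrix.shape[0] < 2:
            raise ValueError("alignment needs at least 2 rows")

    @classmethod
    def from_strings(cls, ids: Sequence[str], rows: Sequence[str]) -> "AlignmentMatrix":
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            detail = ", ".join(f"{i}:{len(r)}" for i, r in zip(ids, rows))
            raise ParseError(f"ragged alignment rows (lengths {detail})")
        mat = np.vstack([encode(r) for r in rows])
        return cls(list(ids), mat)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def row(self, rec_id: str) -> str:
        try:
            idx = self.ids.index(rec_id)
        except ValueError:
            raise KeyError(f"id {rec_id!r} not in alignment") from None
        return self.matrix[idx].tobytes().decode("ascii")


@dataclass
class ReportTable:
    """A rectangular table destined for a TSV report.

    Rows keep Python-typed cells; floats are formatted to 5 decimals on
    write. Row order must be deterministic — builders sort explicitly.
    """

    name: str
    header: list[str]
    rows: list[list] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.rows:
            if len(r) != len(self.header):
                raise ValueError(
                    f"table {self.name!r}: row width {len(r)} != header {len(self.header)}"
                )


def _norm_seq(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read genome FASTA; uppercases, maps U->T, rejects gaps and duplicates."""
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, _norm_seq(str(rec.seq))).validate())
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_alignment(path: str | Path) -> AlignmentMatrix:
    """Read an aligned FASTA into an AlignmentMatrix (rows in file order)."""
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seq = _norm_seq(str(rec.seq))
        SeqRecord(rec.id, seq).validate(aligned=True)
        ids.append(rec.id)
        rows.append(seq)
    if len(ids) < 2:
        raise ParseError(f"{path}: alignment needs at least 2 sequences")
    return AlignmentMatrix.from_strings(ids, rows)


def write_alignment(aln: AlignmentMatrix, path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, rec_id in enumerate(aln.ids):
            fh.write(f">{rec_id}\n")
            row = aln.matrix[i].tobytes().decode("ascii")
            for j in range(0, len(row), width):
                fh.write(row[j : j + width] + "\n")


def _gff_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_features(path: str | Path, genome_length: int | None = None) -> list[GeneFeature]:
    """Read gene features from GFF3 or a simple tab feature table.

    GFF3: lines with type CDS/tRNA/rRNA are kept, grouped into one
    GeneFeature per gene symbol (attribute ``gene``, else ``Name``, else
    ``ID``); multi-line genes become multi-part features (introns implied).
    Other feature types are ignored with a logged count.

    The plain table dialect has columns (name, kind, start, end, strand)
    with 1-based inclusive coordinates, '#' comments allowed.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    grouped: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    order: list[tuple[str, str]] = []
    ignored = 0

    def add(name: str, kind: str, start1: int, end1: int, strand: str) -> None:
        if end1 < start1:
            raise ParseError(f"{path}: feature {name!r} has end < start ({start1}..{end1})")
        start, end = start1 - 1, end1  # to 0-based half-open
        if genome_length is not None and end > 2 * genome_length:
            raise ParseError(f"{path}: feature {name!r} beyond sequence length")
        key = (name, kind)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append((start, end, strand))

    is_gff = text.lstrip().startswith("##gff") or path.suffix.lower() in {".gff", ".gff3"}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if is_gff:
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            kind = fields[2]
            if kind not in FEATURE_KINDS:
                ignored += 1
                continue
            attrs = _gff_attributes(fields[8])
            name = attrs.get("gene") or attrs.get("Name") or attrs.get("ID")
            if not name:
                raise ParseError(f"{path}:{lineno}: no gene/Name/ID attribute")
            add(name, kind, int(fields[3]), int(fields[4]), fields[6])
        else:
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns (name kind start end strand)")
            name, kind = fields[0], fields[1]
            if kind not in FEATURE_KINDS:
                ignored += 1
                continue
            add(name, kind, int(fields[2]), int(fields[3]), fields[4])

    if ignored:
        log.info("read_features: ignored %d features outside %s", ignored, FEATURE_KINDS)
    features = []
    for name, kind in order:
        parts = sorted(grouped[(name, kind)])
        if parts[0][2] == "-":
            parts = parts[::-1]  # order along transcription
        features.append(GeneFeature(name, kind, parts))
    return features


def write_features_gff3(
    features: Iterable[GeneFeature], path: str | Path, seqid: str = "genome"
) -> None:
    """Write features as GFF3 (one line per exon part, gene= attribute)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            for start, end, strand in feat.parts:
                fh.write(
                    f"{seqid}\tplastidkit\t{feat.kind}\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                    f"gene={feat.name}\n"
                )


def format_cell(value) -> str:
    """Report cell formatting: floats to 5 decimals, everything else str()."""
    if isinstance(value, float) or isinstance(value, np.floating):
        return f"{value:.5f}"
    return str(value)


def write_report(table: ReportTable, path: str | Path) -> None:
    """Write a ReportTable as a UTF-8 TSV, header first, '\\n' endings."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(table.header) + "\n")
        for row in table.rows:
            fh.write("\t".join(format_cell(c) for c in row) + "\n")


def read_report(path: str | Path) -> ReportTable:
    """Re-read a written report; cells come back as strings."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty report")
    header = lines[0].split("\t")
    rows = [line.split("\t") for line in lines[1:]]
    return ReportTable(path.stem, header, rows)
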