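"""Readers and writers for the formats the pipeline touches.

FASTA genomic input, GFF3 annotation output, the tab-separated truth
tables shared with the synthetic-cluster generator, and JSON summaries.
Internal coordinates are 0-based half-open on the forward strand;
conversion to 1-based inclusive happens only at the GFF3/TSV boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: column order of the truth-table dialect
TRUTH_COLUMNS = (
    "seq_id",
    "name",
    "subunit",
    "status",
    "bohr_status",
    "strand",
    "exon1",
    "exon2",
    "exon3",
    "defects",
)


def revcomp(residues: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return residues.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed or invariant-violating input."""


@dataclass(frozen=True)
class GenomicSequence:
    """A named nucleotide sequence (uppercase, alphabet {A,C,G,T,N})."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        bad = set(self.residues) - NUCLEOTIDE_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.residues) if c in bad
            )
            raise FormatError(
                f"alphabet violation in {self.id!r}: "
                f"{self.residues[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "GenomicSequence":
        return GenomicSequence(self.id, revcomp(self.residues))


@dataclass
class AnnotationRecord:
    """One GFF3-style feature on a genomic sequence.

    ``start``/``end`` are 1-based inclusive (the external convention);
    ``attributes`` carries ID/Parent links and classification metadata.
    """

    seq_id: str
    feature_type: str  # gene | pseudogene | exon | CDS
    start: int
    end: int
    strand: str  # '+' or '-'
    attributes: dict[str, str] = field(default_factory=dict)

    def validate(self, seq_lengths: dict[str, int] | None = None) -> None:
        if self.feature_type not in {"gene", "pseudogene", "exon", "CDS"}:
            raise FormatError(f"unknown feature type {self.feature_type!r}")
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"coordinate invariant violated by {self!r}: "
                f"need 1 <= start <= end"
            )
        if seq_lengths is not None:
            if self.seq_id not in seq_lengths:
                raise FormatError(f"unknown sequence {self.seq_id!r}")
            if self.end > seq_lengths[self.seq_id]:
                raise FormatError(
                    f"record {self!r} extends past end of {self.seq_id!r}"
                )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"bad strand {self.strand!r}")
        if self.feature_type in {"exon", "CDS"} and "Parent" not in self.attributes:
            raise FormatError(
                f"{self.feature_type} record without Parent attribute: {self!r}"
            )


def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read FASTA into GenomicSequence records.

    Residues are uppercased and U mapped to T.  Errors: empty file,
    duplicate ids, characters outside {A,C,G,T,N,U}.
    """
    records: list[GenomicSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("U", "T")
        records.append(GenomicSequence(rec.id, residues))
    if not records:
        raise FormatError(f"no records in {path}")
    return records


def write_fasta(seqs: Iterable[GenomicSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_FEATURE_RANK = {"gene": 0, "pseudogene": 0, "exon": 1, "CDS": 2}

_ESCAPES = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09"}


def _escape(value: str) -> str:
    for raw, esc in _ESCAPES.items():
        value = value.replace(raw, esc)
    return value


def _unescape(value: str) -> str:
    for raw, esc in _ESCAPES.items():
        value = value.replace(esc, raw)
    return value


def _format_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    keys = [k for k in ("ID", "Parent", "Name") if k in attrs]
    keys += sorted(k for k in attrs if k not in {"ID", "Parent", "Name"})
    return ";".join(f"{k}={_escape(str(attrs[k]))}" for k in keys)


def write_gff3(
    records: list[AnnotationRecord],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
    source: str = "hbcluster",
) -> None:
    """Write records as GFF3, ordered by (seq_id, start, feature rank)."""
    for rec in records:
        rec.validate(seq_lengths)
    ordered = sorted(
        records,
        key=lambda r: (r.seq_id, r.start, _FEATURE_RANK[r.feature_type], r.end,
                       r.attributes.get("ID", r.attributes.get("Parent", ""))),
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seq_lengths:
            for sid in sorted(seq_lengths):
                fh.write(f"##sequence-region {sid} 1 {seq_lengths[sid]}\n")
        for rec in ordered:
            fh.write(
                "\t".join(
                    [
                        rec.seq_id,
                        source,
                        rec.feature_type,
                        str(rec.start),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        _format_attributes(rec.attributes),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Parse a GFF3 file written by :func:`write_gff3` (round-trip reader)."""
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"expected 9 columns, got {len(cols)}: {line!r}")
            attrs: dict[str, str] = {}
            if cols[8] != ".":
                for kv in cols[8].split(";"):
                    k, _, v = kv.partition("=")
                    attrs[k] = _unescape(v)
            records.append(
                AnnotationRecord(
                    seq_id=cols[0],
                    feature_type=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Truth tables

@dataclass
class TruthRecord:
    """Planted ground truth for one synthetic gene.

    Exon intervals are 0-based half-open forward-strand coordinates in
    transcription (exon-number) order; a missing exon is ``None``.
    """

    seq_id: str
    name: str
    subunit: str  # alpha | beta
    status: str  # functional | pseudogene
    bohr_status: str  # bohr | non_bohr | not_applicable
    strand: str
    exons: list[tuple[int, int] | None]
    defects: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        present = [iv for iv in self.exons if iv is not None]
        return min(s for s, _ in present), max(e for _, e in present)


def _interval_to_text(iv: tuple[int, int] | None) -> str:
    if iv is None:
        return "."
    return f"{iv[0] + 1}-{iv[1]}"  # 1-based inclusive at the boundary


def _interval_from_text(text: str) -> tuple[int, int] | None:
    if text == ".":
        return None
    a, _, b = text.partition("-")
    return int(a) - 1, int(b)


def write_truth_table(records: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for r in records:
            exons = list(r.exons) + [None] * (3 - len(r.exons))
            writer.writerow(
                [
                    r.seq_id,
                    r.name,
                    r.subunit,
                    r.status,
                    r.bohr_status,
                    r.strand,
                    _interval_to_text(exons[0]),
                    _interval_to_text(exons[1]),
                    _interval_to_text(exons[2]),
                    ",".join(r.defects) if r.defects else ".",
                ]
            )


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    """Read a generator truth table; errors name any missing column."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in TRUTH_COLUMNS:
            if col not in header:
                raise FormatError(f"truth table missing mandatory column {col!r}")
        records = []
        for row in reader:
            for col in ("subunit", "status", "strand"):
                if not row.get(col):
                    raise FormatError(f"truth table row missing value for {col!r}")
            records.append(
                TruthRecord(
                    seq_id=row["seq_id"],
                    name=row["name"],
                    subunit=row["subunit"],
                    status=row["status"],
                    bohr_status=row["bohr_status"],
                    strand=row["strand"],
                    exons=[
                        _interval_from_text(row["exon1"]),
                        _interval_from_text(row["exon2"]),
                        _interval_from_text(row["exon3"]),
                    ],
                    defects=[] if row["defects"] == "." else row["defects"].split(","),
                )
            )
    return records


def write_json_summary(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
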