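"""End-to-end annotation: find -> chain -> refine -> classify -> layout -> name.

Also provides the truth-table comparison used to validate runs on
synthetic clusters, and GFF3/JSON export of classified genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classifier import ClassifiedGene, classify, counts_dict, summarize_counts
from .finder import FinderConfig, find_genes
from .io_formats import (
    AnnotationRecord,
    GenomicSequence,
    TruthRecord,
    write_gff3,
    write_json_summary,
)
from .layout import ClusterReport, assign_names, build_layout
from .reference import GlobinReference

logger = logging.getLogger("hbcluster")


@dataclass
class AnnotateResult:
    seq: GenomicSequence
    genes: list[ClassifiedGene]
    report: ClusterReport
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)


def annotate_sequence(
    seq: GenomicSequence,
    ref: GlobinReference,
    config: FinderConfig | None = None,
    chromosome_label: str | None = None,
    used_labels: set[str] | None = None,
) -> AnnotateResult:
    """Annotate one sequence and name its genes 5'->3'."""
    config = config or FinderConfig()
    logger.info("annotating %s (%d bp) with thresholds %s", seq.id, len(seq), config.as_dict())
    models = find_genes(seq, ref, config)
    genes = [classify(m, ref.config) for m in models]
    report = build_layout(genes) if genes else ClusterReport(seq_id=seq.id, ordered_genes=[])
    label = chromosome_label or seq.id
    assign_names(report, label, used_labels)
    result = AnnotateResult(seq=seq, genes=report.ordered_genes, report=report)
    result.counts = summarize_counts(result.genes)
    logger.info("%s: %s", seq.id, counts_dict(result.genes))
    return result


def annotate_many(
    seqs: list[GenomicSequence],
    ref: GlobinReference,
    config: FinderConfig | None = None,
    labels: dict[str, str] | None = None,
) -> list[AnnotateResult]:
    used: set[str] = set()
    labels = labels or {}
    return [
        annotate_sequence(s, ref, config, labels.get(s.id), used_labels=used)
        for s in seqs
    ]


# ---------------------------------------------------------------------------
# export


def to_annotation_records(genes: list[ClassifiedGene]) -> list[AnnotationRecord]:
    """GFF3-style records (1-based inclusive) for classified genes."""
    records: list[AnnotationRecord] = []
    for gene in genes:
        feature = "gene" if gene.status == "functional" else "pseudogene"
        s, e = gene.span
        attrs = {
            "ID": gene.name,
            "Name": gene.name,
            "subunit": gene.subunit,
            "status": gene.status,
            "bohr_status": gene.bohr_status,
        }
        if gene.defects:
            attrs["defects"] = ",".join(gene.defects)
        records.append(
            AnnotationRecord(gene.seq_id, feature, s + 1, e, gene.strand, attrs)
        )
        for k, (xs, xe) in zip(gene.model.exon_indices, gene.model.exons):
            for ftype in ("exon", "CDS"):
                records.append(
                    AnnotationRecord(
                        gene.seq_id,
                        ftype,
                        xs + 1,
                        xe,
                        gene.strand,
                        {
                            "ID": f"{gene.name}.{ftype.lower()}{k}",
                            "Parent": gene.name,
                        },
                    )
                )
    return records


def genes_table(genes: list[ClassifiedGene]) -> pd.DataFrame:
    """Flat per-gene report (location in kb, strand, classification,
    defect notes). EST-support columns are intentionally absent: they
    would require external database lookups."""
    rows = []
    for g in genes:
        s, e = g.span
        rows.append(
            {
                "seq_id": g.seq_id,
                "name": g.name,
                "subunit": g.subunit,
                "status": g.status,
                "bohr_status": g.bohr_status,
                "strand": g.strand,
                "location_kb": round(s / 1000, 1),
                "start": s + 1,
                "end": e,
                "n_exons": len(g.model.exon_indices),
                "protein_length": g.model.protein_length,
                "failed_criteria": ",".join(sorted(g.failed_criteria)) or ".",
                "defects": ",".join(g.defects) or ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "name", "subunit", "status", "bohr_status", "strand",
            "location_kb", "start", "end", "n_exons", "protein_length",
            "failed_criteria", "defects",
        ],
    )


def write_outputs(results: list[AnnotateResult], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_genes = [g for r in results for g in r.genes]
    seq_lengths = {r.seq.id: len(r.seq) for r in results}
    paths = {
        "gff3": outdir / "annotation.gff3",
        "genes": outdir / "genes.tsv",
        "counts": outdir / "counts.tsv",
        "summary": outdir / "summary.json",
        "layout": outdir / "layout.json",
    }
    write_gff3(to_annotation_records(all_genes), paths["gff3"], seq_lengths)
    genes_table(all_genes).to_csv(paths["genes"], sep="\t", index=False)
    summarize_counts(all_genes).to_csv(paths["counts"], sep="\t", index=False)
    write_json_summary(
        {
            "per_sequence": {r.seq.id: counts_dict(r.genes) for r in results},
            "total": counts_dict(all_genes),
        },
        paths["summary"],
    )
    layout_report: dict = {r.seq.id: r.report.as_dict() for r in results}
    if len(results) > 1:
        # per-contig layout; relative contig order is not inferred
        layout_report["contig_order"] = "tentative"
    write_json_summary(layout_report, paths["layout"])
    return paths


# ---------------------------------------------------------------------------
# contig ordering (multi-contig assemblies)


def read_contig_order(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a contig-order TSV (contig, rank, orientation: +/-).

    The pipeline never infers contig order for multi-contig input;
    an explicit file like this is the supported route (e.g. an order
    established by homology against a finished assembly).
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "rank": int, "orientation": str})
    missing = {"contig", "rank", "orientation"} - set(df.columns)
    if missing:
        raise ValueError(f"contig-order file missing column(s) {sorted(missing)}")
    return list(df[["contig", "rank", "orientation"]].itertuples(index=False, name=None))


def apply_contig_order(
    seqs: list[GenomicSequence], order: list[tuple[str, int, str]]
) -> list[GenomicSequence]:
    """Reorder contigs by rank and flip those marked '-'.

    Contigs absent from the order file keep their input order after
    the ranked ones.
    """
    by_id = {s.id: s for s in seqs}
    ranked: list[GenomicSequence] = []
    seen: set[str] = set()
    for contig, _, orientation in sorted(order, key=lambda t: t[1]):
        if contig not in by_id:
            raise ValueError(f"contig order names unknown contig {contig!r}")
        seq = by_id[contig]
        ranked.append(seq.reverse_complement() if orientation == "-" else seq)
        seen.add(contig)
    ranked.extend(s for s in seqs if s.id not in seen)
    return ranked


# ---------------------------------------------------------------------------
# truth comparison (synthetic clusters)


@dataclass
class TruthComparison:
    n_truth: int
    n_predicted: int
    n_matched: int
    n_agree: int
    mismatches: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.n_agree / self.n_truth if self.n_truth else 1.0

    @property
    def perfect(self) -> bool:
        return (
            self.n_truth == self.n_predicted == self.n_matched == self.n_agree
        )


def compare_to_truth(
    genes: list[ClassifiedGene], truth: list[TruthRecord]
) -> TruthComparison:
    """Match predictions to planted genes by overlap and compare
    subunit, status, Bohr status and strand gene-by-gene."""
    cmp = TruthComparison(n_truth=len(truth), n_predicted=len(genes), n_matched=0, n_agree=0)
    used: set[int] = set()
    for rec in truth:
        ts, te = rec.span
        match = None
        for i, g in enumerate(genes):
            if i in used:
                continue
            gs, ge = g.span
            if gs < te and ts < ge:
                match = i
                break
        if match is None:
            cmp.mismatches.append(f"{rec.name}: not recovered")
            continue
        used.add(match)
        cmp.n_matched += 1
        g = genes[match]
        fields = (
            ("subunit", g.subunit, rec.subunit),
            ("status", g.status, rec.status),
            ("bohr_status", g.bohr_status, rec.bohr_status),
            ("strand", g.strand, rec.strand),
        )
        bad = [f"{name}: {got} != {want}" for name, got, want in fields if got != want]
        if bad:
            cmp.mismatches.append(f"{rec.name}: " + "; ".join(bad))
        else:
            cmp.n_agree += 1
    for i, g in enumerate(genes):
        if i not in used:
            cmp.mismatches.append(f"spurious model at {g.seq_id}:{g.span}")
    return cmp
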