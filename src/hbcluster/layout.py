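"""Cluster layout analysis and gene naming.

Salmon hemoglobin clusters carry alpha and beta genes in alternating
order with the two subunits transcribed toward each other (alpha on the
negative strand, beta on the positive), so adjacent genes meet 3' end
to 3' end ("tail-to-tail").  This module orders classified genes along
a sequence, scores deviations from that expectation, counts the
tail-to-tail pair motif, and assigns names of the form
``Ssa<ChrLabel><subunit symbol><k>`` (pseudogenes get a psi marker and
an independent counter), numbering 5' to 3' within each subunit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier import PSEUDOGENE, ClassifiedGene

EXPECTED_STRAND = {"alpha": "-", "beta": "+"}
SUBUNIT_SYMBOL = {"alpha": "α", "beta": "β"}
PSEUDO_MARK = "ψ"


@dataclass
class ClusterReport:
    seq_id: str
    ordered_genes: list[ClassifiedGene]
    strand_violations: list[ClassifiedGene] = field(default_factory=list)
    alternation_violations: list[tuple[ClassifiedGene, ClassifiedGene]] = field(
        default_factory=list
    )
    orientation_motif_count: int = 0
    includes_pseudogenes: bool = True

    def as_dict(self) -> dict:
        return {
            "seq_id": self.seq_id,
            "n_genes": len(self.ordered_genes),
            "gene_order": [
                {
                    "name": g.name,
                    "subunit": g.subunit,
                    "status": g.status,
                    "bohr_status": g.bohr_status,
                    "strand": g.strand,
                    "start": g.span[0] + 1,
                    "end": g.span[1],
                }
                for g in self.ordered_genes
            ],
            "strand_violations": [g.name for g in self.strand_violations],
            "alternation_violations": [
                [a.name, b.name] for a, b in self.alternation_violations
            ],
            "tail_to_tail_pairs": self.orientation_motif_count,
            "includes_pseudogenes": self.includes_pseudogenes,
        }


def build_layout(
    genes: list[ClassifiedGene], include_pseudogenes: bool = True
) -> ClusterReport:
    """Order genes 5'->3' and score layout disruptions.

    Pseudogenes take part in the alternation and strand checks by
    default; ``include_pseudogenes=False`` restricts every check to
    putatively functional genes.
    """
    if not genes:
        return ClusterReport(seq_id="", ordered_genes=[])
    seq_ids = {g.seq_id for g in genes}
    if len(seq_ids) != 1:
        raise ValueError(f"genes span multiple sequences: {sorted(seq_ids)}")
    pool = [g for g in genes if include_pseudogenes or g.status != PSEUDOGENE]
    ordered = sorted(pool, key=lambda g: g.span)
    report = ClusterReport(
        seq_id=seq_ids.pop(),
        ordered_genes=ordered,
        includes_pseudogenes=include_pseudogenes,
    )
    report.strand_violations = [
        g for g in ordered if g.strand != EXPECTED_STRAND[g.subunit]
    ]
    for a, b in zip(ordered, ordered[1:]):
        if a.subunit == b.subunit:
            report.alternation_violations.append((a, b))
        if a.strand == "+" and b.strand == "-":
            report.orientation_motif_count += 1
    return report


def assign_names(
    report: ClusterReport,
    chromosome_label: str,
    used_labels: set[str] | None = None,
) -> list[ClassifiedGene]:
    """Name genes in 5'->3' order within subunit.

    Functional genes and pseudogenes count on independent counters
    (e.g. ``SsaChr6alpha1`` vs ``SsaChr6alpha-psi-1``, written with the
    Greek symbols).  ``used_labels`` guards against reusing a
    chromosome label across calls.
    """
    if used_labels is not None:
        if chromosome_label in used_labels:
            raise ValueError(f"chromosome label {chromosome_label!r} already used")
        used_labels.add(chromosome_label)
    counters: dict[tuple[str, bool], int] = {}
    for gene in report.ordered_genes:
        pseudo = gene.status == PSEUDOGENE
        key = (gene.subunit, pseudo)
        counters[key] = counters.get(key, 0) + 1
        symbol = SUBUNIT_SYMBOL[gene.subunit] + (PSEUDO_MARK if pseudo else "")
        gene.name = f"Ssa{chromosome_label}{symbol}{counters[key]}"
    names = [g.name for g in report.ordered_genes]
    if len(set(names)) != len(names):
        raise AssertionError("naming produced duplicates")
    return report.ordered_genes
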