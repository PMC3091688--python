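"""Rule-based classification of refined gene models.

A refined model is putatively functional only if it passes all three
criteria: (1) exactly three exons and two introns; (2) exon sizes and
termini are appropriate — canonical splice junctions, start and stop
codons in place, no internal stops or frameshifts, exon peptide lengths
within the template ranges; (3) the predicted protein is 143 residues
for an alpha chain or 147/148 for a beta chain.  Any failure makes the
model a putative pseudogene, with the failed criteria and defect labels
preserved for audit.  Functional beta chains are additionally screened
for the three non-Bohr hallmarks (147 residues including the initiator
methionine, C-terminal phenylalanine, alanine at position 93); the
hallmarks are conjunctive — a beta chain missing any of them is an
ordinary Bohr globin, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .finder import GeneModel
from .reference import ClassifierConfig

FUNCTIONAL = "functional"
PSEUDOGENE = "pseudogene"

BOHR = "bohr"
NON_BOHR = "non_bohr"
NOT_APPLICABLE = "not_applicable"

CRITERIA = ("exon_count", "splice_and_termini", "protein_length")
HALLMARKS = ("length_147", "cterm_phe", "ala_93")


@dataclass
class ClassifiedGene:
    model: GeneModel
    status: str = FUNCTIONAL
    failed_criteria: set[str] = field(default_factory=set)
    bohr_status: str = NOT_APPLICABLE
    hallmarks_met: set[str] = field(default_factory=set)
    name: str = ""

    # convenience passthroughs
    @property
    def seq_id(self) -> str:
        return self.model.seq_id

    @property
    def subunit(self) -> str:
        return self.model.subunit

    @property
    def strand(self) -> str:
        return self.model.strand

    @property
    def start(self) -> int:
        return self.model.start

    @property
    def span(self) -> tuple[int, int]:
        return self.model.span

    @property
    def defects(self) -> list[str]:
        return self.model.defects


def classify_functionality(
    model: GeneModel, cfg: ClassifierConfig | None = None
) -> ClassifiedGene:
    """Apply the three functionality criteria to a refined model."""
    if not model.refined:
        raise ValueError("refine first: classify_functionality needs a refined model")
    cfg = cfg or ClassifierConfig()
    failed: set[str] = set()

    if len(model.exon_indices) != cfg.required_exon_count or len(
        model.intron_intervals
    ) != cfg.required_intron_count:
        failed.add("exon_count")

    termini_defects = {
        "bad_splice_donor",
        "bad_splice_acceptor",
        "internal_stop",
        "frameshift",
        "no_start",
        "no_stop",
    }
    if (
        termini_defects & set(model.defects)
        or not all(ok for pair in model.splice_ok for ok in pair)
        or not model.has_start
        or not model.has_stop
        or not all(model.exon_size_ok)
    ):
        failed.add("splice_and_termini")

    if model.protein_length not in cfg.expected_protein_lengths(model.subunit):
        failed.add("protein_length")

    status = FUNCTIONAL if not failed else PSEUDOGENE
    return ClassifiedGene(model=model, status=status, failed_criteria=failed)


def classify_bohr(
    gene: ClassifiedGene, cfg: ClassifierConfig | None = None
) -> ClassifiedGene:
    """Screen a classified gene for the non-Bohr beta hallmarks."""
    cfg = cfg or ClassifierConfig()
    if gene.subunit != "beta" or gene.status != FUNCTIONAL:
        gene.bohr_status = NOT_APPLICABLE
        gene.hallmarks_met = set()
        return gene
    protein = gene.model.protein
    met: set[str] = set()
    if len(protein) == cfg.nonbohr_protein_length:
        met.add("length_147")
    if protein.endswith(cfg.nonbohr_cterm_residue):
        met.add("cterm_phe")
    pos = cfg.nonbohr_position - (1 if cfg.nonbohr_position_includes_met else 0)
    if pos < len(protein) and protein[pos] == cfg.nonbohr_position_residue:
        met.add("ala_93")
    gene.hallmarks_met = met
    gene.bohr_status = NON_BOHR if met == set(HALLMARKS) else BOHR
    return gene


def classify(model: GeneModel, cfg: ClassifierConfig | None = None) -> ClassifiedGene:
    """Functionality criteria followed by the Bohr screen."""
    return classify_bohr(classify_functionality(model, cfg), cfg)


def summarize_counts(genes: list[ClassifiedGene]) -> pd.DataFrame:
    """Per-sequence and total counts by (subunit, status, bohr_status).

    Rows are deterministic: every (subunit, status, bohr_status) cell of
    the rule table appears, in fixed order, for each sequence and for
    the ``total`` aggregate.
    """
    cells = [
        ("alpha", FUNCTIONAL, NOT_APPLICABLE),
        ("alpha", PSEUDOGENE, NOT_APPLICABLE),
        ("beta", FUNCTIONAL, BOHR),
        ("beta", FUNCTIONAL, NON_BOHR),
        ("beta", PSEUDOGENE, NOT_APPLICABLE),
    ]
    seq_ids = sorted({g.seq_id for g in genes})
    rows = []
    for sid in seq_ids + ["total"]:
        pool = genes if sid == "total" else [g for g in genes if g.seq_id == sid]
        for subunit, status, bohr in cells:
            n = sum(
                1
                for g in pool
                if g.subunit == subunit
                and g.status == status
                and g.bohr_status == bohr
            )
            rows.append(
                {
                    "seq_id": sid,
                    "subunit": subunit,
                    "status": status,
                    "bohr_status": bohr,
                    "count": n,
                }
            )
    return pd.DataFrame(rows, columns=["seq_id", "subunit", "status", "bohr_status", "count"])


def counts_dict(genes: list[ClassifiedGene]) -> dict[str, int]:
    """Total counts keyed by category name (JSON-friendly)."""
    return {
        "alpha_functional": sum(
            1 for g in genes if g.subunit == "alpha" and g.status == FUNCTIONAL
        ),
        "alpha_pseudogene": sum(
            1 for g in genes if g.subunit == "alpha" and g.status == PSEUDOGENE
        ),
        "beta_functional": sum(
            1 for g in genes if g.subunit == "beta" and g.status == FUNCTIONAL
        ),
        "beta_nonbohr": sum(1 for g in genes if g.bohr_status == NON_BOHR),
        "beta_pseudogene": sum(
            1 for g in genes if g.subunit == "beta" and g.status == PSEUDOGENE
        ),
    }
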