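"""Structural expectations and exon templates for globin genes.

Vertebrate hemoglobin subunit genes share a three-exon/two-intron
structure with both introns falling between codons (phase 0), canonical
GT donor and AG acceptor dinucleotides, and tightly conserved protein
lengths: 143 residues for alpha chains and 147 or 148 for beta chains
(lengths counted including the initiator methionine).  The salmon
non-Bohr beta chain is diagnosed by three hallmarks: a length of 147
residues including the initiator methionine, a C-terminal phenylalanine
in place of the Bohr-proton histidine, and alanine at position 93.
Every rule constant the classifier applies lives in
:class:`ClassifierConfig`; candidate genes are located by aligning the
per-exon peptide/CDS templates held in :class:`GlobinReference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_formats import FormatError, read_fasta

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})


def translate(cds: str, phase: int = 0) -> str:
    """Translate under the standard genetic code.

    Stops are rendered ``*`` and never truncated (defect detection needs
    them); codons containing N or other ambiguity render as ``X``; a
    partial trailing codon is ignored.
    """
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    s = cds[phase:]
    return "".join(
        _CODON_TO_AA.get(s[i : i + 3], "X")
        for i in range(0, len(s) - len(s) % 3, 3)
    )


@dataclass(frozen=True)
class ClassifierConfig:
    """Rule constants for functionality and Bohr-status classification.

    Protein lengths and the non-Bohr position are counted 1-based
    including the initiator methionine (``nonbohr_position_includes_met``
    makes the position-93 convention switchable).
    """

    required_exon_count: int = 3
    required_intron_count: int = 2
    alpha_protein_length: int = 143
    beta_protein_lengths: frozenset[int] = frozenset({147, 148})
    nonbohr_protein_length: int = 147
    nonbohr_cterm_residue: str = "F"
    nonbohr_position: int = 93
    nonbohr_position_residue: str = "A"
    nonbohr_position_includes_met: bool = True
    donor_dinucleotide: str = "GT"
    acceptor_dinucleotide: str = "AG"
    exon_length_slack: int = 2  # residues of tolerance on exon peptide sizes

    def __post_init__(self) -> None:
        lengths = (
            self.required_exon_count,
            self.required_intron_count,
            self.alpha_protein_length,
            self.nonbohr_protein_length,
            *self.beta_protein_lengths,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all structural lengths must be positive")
        if self.nonbohr_protein_length not in self.beta_protein_lengths:
            raise ValueError(
                "nonbohr_protein_length must be one of beta_protein_lengths"
            )
        if not 0 < self.nonbohr_position < self.nonbohr_protein_length:
            raise ValueError(
                "nonbohr_position must fall inside the non-Bohr protein"
            )

    def expected_protein_lengths(self, subunit: str) -> frozenset[int]:
        if subunit == "alpha":
            return frozenset({self.alpha_protein_length})
        if subunit == "beta":
            return frozenset(self.beta_protein_lengths)
        raise ValueError(f"unknown subunit {subunit!r}")


@dataclass(frozen=True)
class ExonTemplate:
    """One exon exemplar: peptide, CDS and the expected size range."""

    subunit: str  # alpha | beta
    exon_index: int  # 1..3
    peptide: str
    cds: str
    phase: int = 0
    expected_peptide_length_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.exon_index not in (1, 2, 3):
            raise ValueError(f"exon_index must be 1..3, got {self.exon_index}")
        if translate(self.cds, self.phase) != self.peptide:
            raise FormatError(
                f"template inconsistency: CDS of {self.subunit} exon "
                f"{self.exon_index} does not translate to its peptide"
            )
        if self.expected_peptide_length_range is None:
            n = len(self.peptide)
            object.__setattr__(
                self, "expected_peptide_length_range", (n - 2, n + 2)
            )


@dataclass
class GlobinReference:
    """Exon templates per subunit variant plus the classifier config.

    ``templates`` maps a variant name (``alpha``, ``beta``,
    ``beta_nonbohr``) to its three exon templates keyed by exon index.
    """

    templates: dict[str, dict[int, ExonTemplate]]
    config: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        for variant, exons in self.templates.items():
            missing = {1, 2, 3} - set(exons)
            if missing:
                raise FormatError(
                    f"incomplete template set: variant {variant!r} lacks "
                    f"exon(s) {sorted(missing)}"
                )

    @property
    def variants(self) -> list[str]:
        return sorted(self.templates)

    def subunit_of(self, variant: str) -> str:
        return self.templates[variant][1].subunit

    def exon(self, variant: str, index: int) -> ExonTemplate:
        return self.templates[variant][index]

    def cds(self, variant: str) -> str:
        return "".join(self.templates[variant][i].cds for i in (1, 2, 3))

    def protein(self, variant: str) -> str:
        return "".join(self.templates[variant][i].peptide for i in (1, 2, 3))


# ---------------------------------------------------------------------------
# Bundle I/O (exon peptide FASTA + exon CDS FASTA + config.yaml)

_CONFIG_FILE = "config.yaml"
_PEPTIDE_FILE = "exon_peptides.fasta"
_CDS_FILE = "exon_cds.fasta"


def _parse_exon_fasta(path: Path) -> dict[tuple[str, int], str]:
    out: dict[tuple[str, int], str] = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        variant, _, exon = rec.id.partition(".exon")
        if not exon.isdigit():
            raise FormatError(f"bad template id {rec.id!r} in {path.name}")
        out[(variant, int(exon))] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"no records in {path}")
    return out


def load_reference(path: str | Path) -> GlobinReference:
    """Load a reference bundle directory.

    Expects ``exon_peptides.fasta`` and ``exon_cds.fasta`` with record
    ids ``<variant>.exon<i>`` plus a ``config.yaml`` mirroring
    :class:`ClassifierConfig` field names.
    """
    path = Path(path)
    peptides = _parse_exon_fasta(path / _PEPTIDE_FILE)
    cdss = _parse_exon_fasta(path / _CDS_FILE)
    cfg_raw = yaml.safe_load((path / _CONFIG_FILE).read_text()) or {}
    subunits = cfg_raw.pop("subunit_of_variant", {})
    if "beta_protein_lengths" in cfg_raw:
        cfg_raw["beta_protein_lengths"] = frozenset(cfg_raw["beta_protein_lengths"])
    config = ClassifierConfig(**cfg_raw)

    templates: dict[str, dict[int, ExonTemplate]] = {}
    for (variant, exon_index), pep in sorted(peptides.items()):
        if (variant, exon_index) not in cdss:
            raise FormatError(
                f"incomplete template set: CDS missing for {variant} exon {exon_index}"
            )
        subunit = subunits.get(variant, "beta" if variant.startswith("beta") else "alpha")
        templates.setdefault(variant, {})[exon_index] = ExonTemplate(
            subunit=subunit, exon_index=exon_index, peptide=pep,
            cds=cdss[(variant, exon_index)],
        )
    return GlobinReference(templates=templates, config=config)


def save_reference(ref: GlobinReference, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / _PEPTIDE_FILE, "w") as pep_fh, open(path / _CDS_FILE, "w") as cds_fh:
        for variant in ref.variants:
            for i in (1, 2, 3):
                t = ref.exon(variant, i)
                pep_fh.write(f">{variant}.exon{i}\n{t.peptide}\n")
                cds_fh.write(f">{variant}.exon{i}\n{t.cds}\n")
    cfg = ref.config
    data = {
        "required_exon_count": cfg.required_exon_count,
        "required_intron_count": cfg.required_intron_count,
        "alpha_protein_length": cfg.alpha_protein_length,
        "beta_protein_lengths": sorted(cfg.beta_protein_lengths),
        "nonbohr_protein_length": cfg.nonbohr_protein_length,
        "nonbohr_cterm_residue": cfg.nonbohr_cterm_residue,
        "nonbohr_position": cfg.nonbohr_position,
        "nonbohr_position_residue": cfg.nonbohr_position_residue,
        "nonbohr_position_includes_met": cfg.nonbohr_position_includes_met,
        "donor_dinucleotide": cfg.donor_dinucleotide,
        "acceptor_dinucleotide": cfg.acceptor_dinucleotide,
        "exon_length_slack": cfg.exon_length_slack,
        "subunit_of_variant": {v: ref.subunit_of(v) for v in ref.variants},
    }
    (path / _CONFIG_FILE).write_text(yaml.safe_dump(data, sort_keys=True))


def default_reference() -> GlobinReference:
    """The packaged reference bundle.

    The bundle is synthetic: internally consistent salmon-style alpha,
    Bohr-beta and non-Bohr-beta exon templates generated by
    ``hbcluster.simulate.make_templates`` (fixed seed), standing in for
    a curation of published salmon globin clones.
    """
    bundle = Path(__file__).parent / "data" / "synthetic_salmon_reference"
    return load_reference(bundle)
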