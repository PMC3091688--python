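"""Synthetic globin clusters with exact ground truth.

The generator emulates the statistical structure the annotation
pipeline assumes: alternating alpha/beta three-exon genes in
tail-to-tail orientation (alpha on the negative strand, beta on the
positive), canonical GT..AG introns, configurable background divergence
from the exon templates, planted pseudogenization defects, non-Bohr
beta variants, and random intergenic spacer — plus a truth table that
is exact by construction.  Rule-critical sites (start and stop codons,
splice dinucleotides, non-Bohr hallmark codons) are shielded from
background divergence, and substitutions that would create an in-frame
stop are rejected, so a planted status is never silently flipped; a
soundness self-check re-derives every planted gene from the emitted
sequence at generation time.

The default configuration mirrors the composition of the salmon
chromosome-6 cluster: six functional alpha genes, six functional beta
genes of which two are non-Bohr, two alpha pseudogenes and three beta
pseudogenes, at 5% background divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import GenomicSequence, TruthRecord, revcomp
from .layout import PSEUDO_MARK, SUBUNIT_SYMBOL
from .reference import (
    STOP_CODONS,
    ClassifierConfig,
    ExonTemplate,
    GlobinReference,
    translate,
)

_BASES = "ACGT"

# codons per amino acid under the standard code (stops excluded)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _codon = _b1 + _b2 + _b3
            _aa = translate(_codon)
            if _aa != "*":
                _AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_AMINO_ACIDS = sorted(set(_AA_TO_CODONS) - {"X"})

SUPPORTED_DEFECTS = (
    "missing_exon",
    "bad_splice_donor",
    "bad_splice_acceptor",
    "internal_stop",
    "frameshift",
    "no_start",
    "no_stop",
    "length_violation",
)

# exon peptide lengths (including initiator Met, excluding the stop codon);
# both introns fall between codons, as in vertebrate globin genes
_EXON_LENGTHS = {
    "alpha": (31, 68, 44),  # 143 aa
    "beta": (30, 74, 44),  # 148 aa (Bohr)
    "beta_nonbohr": (30, 74, 43),  # 147 aa
}


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=n))


def _peptide_to_cds(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in peptide
    )


def _split(seq: str, lengths: tuple[int, ...]) -> list[str]:
    parts, pos = [], 0
    for n in lengths:
        parts.append(seq[pos : pos + n])
        pos += n
    return parts


def make_templates(seed: int = 2010) -> GlobinReference:
    """Internally consistent synthetic alpha/beta exon template bundle.

    The alpha chain is 143 residues; the Bohr beta chain is 148
    residues with a C-terminal histidine (the main Bohr-proton donor);
    the non-Bohr beta chain is derived from the Bohr one at ~8%
    peptide divergence, one residue shorter (147), with a C-terminal
    phenylalanine and alanine at position 93.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    cfg = ClassifierConfig()

    alpha_pep = "M" + _random_peptide(rng, sum(_EXON_LENGTHS["alpha"]) - 1)
    beta_pep = list("M" + _random_peptide(rng, sum(_EXON_LENGTHS["beta"]) - 1))
    beta_pep[-1] = "H"  # Bohr-proton C-terminal histidine
    pos93 = cfg.nonbohr_position - 1
    if beta_pep[pos93] == cfg.nonbohr_position_residue:
        beta_pep[pos93] = "S"
    beta_pep = "".join(beta_pep)

    nonbohr = list(beta_pep[:-1])  # 147 residues
    for i in range(1, len(nonbohr)):
        if i not in (pos93, len(nonbohr) - 1) and rng.random() < 0.08:
            nonbohr[i] = _AMINO_ACIDS[rng.integers(len(_AMINO_ACIDS))]
    nonbohr[pos93] = cfg.nonbohr_position_residue
    nonbohr[-1] = cfg.nonbohr_cterm_residue
    nonbohr_pep = "".join(nonbohr)

    templates: dict[str, dict[int, ExonTemplate]] = {}
    for variant, peptide in (
        ("alpha", alpha_pep),
        ("beta", beta_pep),
        ("beta_nonbohr", nonbohr_pep),
    ):
        subunit = "alpha" if variant == "alpha" else "beta"
        exon_peps = _split(peptide, _EXON_LENGTHS[variant])
        templates[variant] = {
            i + 1: ExonTemplate(
                subunit=subunit,
                exon_index=i + 1,
                peptide=pep,
                cds=_peptide_to_cds(rng, pep),
            )
            for i, pep in enumerate(exon_peps)
        }
    return GlobinReference(templates=templates, config=cfg)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cluster.

    Defaults mirror the chromosome-6 cluster composition at 5%
    background divergence; intron and spacer lengths are drawn from the
    compact ranges typical of teleost globin clusters.
    """

    seed: int
    n_alpha_functional: int = 6
    n_beta_bohr: int = 4
    n_beta_nonbohr: int = 2
    pseudogene_plan: tuple[tuple[str, str], ...] = (
        ("alpha", "frameshift"),
        ("alpha", "missing_exon"),
        ("beta", "internal_stop"),
        ("beta", "bad_splice_donor"),
        ("beta", "no_start"),
    )
    template_divergence: float = 0.05
    intron_length_range: tuple[int, int] = (80, 400)
    intergenic_length_range: tuple[int, int] = (2000, 5000)
    gc_content: float = 0.43
    strand_model: str | tuple[str, ...] = "canonical"
    seq_id: str = "synthetic_cluster"
    chromosome_label: str = "Chr6"

    def __post_init__(self) -> None:
        if min(self.n_alpha_functional, self.n_beta_bohr, self.n_beta_nonbohr) < 0:
            raise ValueError("gene counts must be non-negative")
        if not 0 <= self.template_divergence <= 0.2:
            raise ValueError("template_divergence must be in [0, 0.2]")
        for lo, hi in (self.intron_length_range, self.intergenic_length_range):
            if not 0 < lo <= hi:
                raise ValueError("length ranges must be ordered and positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be a fraction")
        for subunit, defect in self.pseudogene_plan:
            if subunit not in ("alpha", "beta"):
                raise ValueError(f"unknown subunit {subunit!r} in pseudogene plan")
            if defect not in SUPPORTED_DEFECTS:
                raise ValueError(f"unsupported defect {defect!r} in pseudogene plan")


def chr6_config(seed: int, **overrides) -> SimulationConfig:
    """The canonical chromosome-6-like composition (the default)."""
    return replace(SimulationConfig(seed=seed), **overrides)


def _random_spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def _mutate_cds(
    cds: str,
    rng: np.random.Generator,
    rate: float,
    protected: set[int],
    forbid_stops: bool = True,
) -> str:
    """Background point substitutions, skipping protected positions and
    any substitution that would create an in-frame stop codon."""
    seq = list(cds)
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hit:
        if pos in protected:
            continue
        old = seq[pos]
        choices = [b for b in _BASES if b != old]
        seq[pos] = choices[rng.integers(3)]
        if forbid_stops:
            c0 = 3 * (pos // 3)
            if "".join(seq[c0 : c0 + 3]) in STOP_CODONS:
                seq[pos] = old
    return "".join(seq)


def _make_intron(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    lo, hi = cfg.intron_length_range
    length = int(rng.integers(lo, hi + 1))
    body = _random_spacer(rng, max(length - 4, 0), cfg.gc_content)
    return "GT" + body + "AG"


def _build_gene(
    rng: np.random.Generator,
    ref: GlobinReference,
    cfg: SimulationConfig,
    variant: str,
    defect: str | None,
) -> tuple[str, list[tuple[int, int] | None]]:
    """One gene in transcription orientation plus relative exon intervals.

    The exon 3 interval includes the stop codon; a missing exon is
    ``None``.
    """
    protected_by_exon: dict[int, set[int]] = {1: {0, 1, 2}, 2: set(), 3: set()}
    if variant == "beta_nonbohr":
        pos93_local = (ref.config.nonbohr_position - 1) - len(ref.exon(variant, 1).peptide)
        protected_by_exon[2] |= {3 * pos93_local + k for k in range(3)}
        last = len(ref.exon(variant, 3).cds)
        protected_by_exon[3] |= {last - 3, last - 2, last - 1}

    exons = {
        i: _mutate_cds(
            ref.exon(variant, i).cds,
            rng,
            cfg.template_divergence,
            protected_by_exon[i],
        )
        for i in (1, 2, 3)
    }
    introns = [_make_intron(rng, cfg), _make_intron(rng, cfg)]
    stop = "TAA"
    missing_exon2 = False

    if defect == "missing_exon":
        missing_exon2 = True
    elif defect == "frameshift":
        pos = int(rng.integers(len(exons[2])))
        exons[2] = exons[2][:pos] + exons[2][pos + 1 :]
    elif defect == "internal_stop":
        cands = []
        for c in range(1, len(exons[2]) // 3 - 1):
            codon = exons[2][3 * c : 3 * c + 3]
            if sum(x != y for x, y in zip(codon, "TAA")) == 1:
                cands.append(c)
        c = cands[rng.integers(len(cands))] if cands else int(
            rng.integers(1, len(exons[2]) // 3 - 1)
        )
        exons[2] = exons[2][: 3 * c] + "TAA" + exons[2][3 * c + 3 :]
    elif defect == "bad_splice_donor":
        introns[0] = "AT" + introns[0][2:]
    elif defect == "bad_splice_acceptor":
        introns[1] = introns[1][:-2] + "AA"
    elif defect == "no_start":
        exons[1] = "GTG" + exons[1][3:]
    elif defect == "no_stop":
        stop = "CAA"
    elif defect == "length_violation":
        c = int(rng.integers(1, len(exons[2]) // 3))
        codon = _AA_TO_CODONS["G"][rng.integers(4)]
        exons[2] = exons[2][: 3 * c] + codon + exons[2][3 * c :]

    parts: list[str] = []
    rel: list[tuple[int, int] | None] = [None, None, None]
    pos = 0

    def push(piece: str) -> tuple[int, int]:
        nonlocal pos
        iv = (pos, pos + len(piece))
        parts.append(piece)
        pos += len(piece)
        return iv

    rel[0] = push(exons[1])
    push(introns[0])
    if not missing_exon2:
        rel[1] = push(exons[2])
        push(introns[1])
    rel[2] = push(exons[3] + stop)
    return "".join(parts), rel


def _interleave(alpha: list, beta: list) -> list:
    """Alternate alpha and beta slots, starting with the larger set."""
    order = []
    a, b = list(alpha), list(beta)
    cur = "beta" if len(b) >= len(a) else "alpha"
    while a or b:
        if (cur == "alpha" and a) or not b:
            order.append(a.pop(0))
        else:
            order.append(b.pop(0))
        cur = "beta" if cur == "alpha" else "alpha"
    return order


def generate_cluster(
    cfg: SimulationConfig, ref: GlobinReference | None = None
) -> tuple[GenomicSequence, list[TruthRecord]]:
    """Emit a synthetic cluster and its exact truth table."""
    ref = ref if ref is not None else make_templates()
    rng = np.random.default_rng(cfg.seed)

    alpha_slots: list[tuple[str, str | None]] = [("alpha", None)] * cfg.n_alpha_functional
    alpha_slots += [("alpha", d) for s, d in cfg.pseudogene_plan if s == "alpha"]
    beta_slots: list[tuple[str, str | None]] = [("beta", None)] * cfg.n_beta_bohr
    beta_slots += [("beta_nonbohr", None)] * cfg.n_beta_nonbohr
    beta_slots += [("beta", d) for s, d in cfg.pseudogene_plan if s == "beta"]
    alpha_slots = [alpha_slots[i] for i in rng.permutation(len(alpha_slots))]
    beta_slots = [beta_slots[i] for i in rng.permutation(len(beta_slots))]
    order = _interleave(alpha_slots, beta_slots)

    if cfg.strand_model == "canonical":
        strands = ["-" if sub == "alpha" else "+" for sub, _ in order]
    else:
        strands = list(cfg.strand_model)
        if len(strands) != len(order):
            raise ValueError("custom strand list length must equal gene count")

    lo, hi = cfg.intergenic_length_range
    parts: list[str] = []
    pos = 0
    truth: list[TruthRecord] = []
    counters: dict[tuple[str, bool], int] = {}

    def push_spacer() -> None:
        nonlocal pos
        spacer = _random_spacer(rng, int(rng.integers(lo, hi + 1)), cfg.gc_content)
        parts.append(spacer)
        pos += len(spacer)

    push_spacer()
    for (variant, defect), strand in zip(order, strands):
        subunit = "alpha" if variant == "alpha" else "beta"
        gene, rel = _build_gene(rng, ref, cfg, variant, defect)
        glen = len(gene)
        if strand == "-":
            parts.append(revcomp(gene))
            exon_ivs = [
                None if iv is None else (pos + glen - iv[1], pos + glen - iv[0])
                for iv in rel
            ]
        else:
            parts.append(gene)
            exon_ivs = [None if iv is None else (pos + iv[0], pos + iv[1]) for iv in rel]
        pos += glen

        pseudo = defect is not None
        key = (subunit, pseudo)
        counters[key] = counters.get(key, 0) + 1
        symbol = SUBUNIT_SYMBOL[subunit] + (PSEUDO_MARK if pseudo else "")
        if pseudo:
            bohr = "not_applicable"
        elif variant == "beta_nonbohr":
            bohr = "non_bohr"
        elif subunit == "beta":
            bohr = "bohr"
        else:
            bohr = "not_applicable"
        truth.append(
            TruthRecord(
                seq_id=cfg.seq_id,
                name=f"Ssa{cfg.chromosome_label}{symbol}{counters[key]}",
                subunit=subunit,
                status="pseudogene" if pseudo else "functional",
                bohr_status=bohr,
                strand=strand,
                exons=exon_ivs,
                defects=[defect] if pseudo else [],
            )
        )
        push_spacer()

    seq = GenomicSequence(cfg.seq_id, "".join(parts))
    _self_check(seq, truth, ref)
    return seq, truth


def _spliced_cds(seq: GenomicSequence, rec: TruthRecord) -> str:
    pieces = []
    for iv in rec.exons:
        if iv is None:
            continue
        s, e = iv
        piece = seq.residues[s:e]
        pieces.append(revcomp(piece) if rec.strand == "-" else piece)
    return "".join(pieces)


def _self_check(
    seq: GenomicSequence, truth: list[TruthRecord], ref: GlobinReference
) -> None:
    """Soundness: re-derive each planted gene from the emitted sequence."""
    cfg = ref.config
    for rec in truth:
        cds = _spliced_cds(seq, rec)
        protein = translate(cds)
        if rec.status == "functional":
            expected = cfg.expected_protein_lengths(rec.subunit)
            ok = (
                cds.startswith("ATG")
                and protein.endswith("*")
                and "*" not in protein[:-1]
                and len(protein) - 1 in expected
            )
            if rec.bohr_status == "non_bohr":
                body = protein[:-1]
                ok = ok and (
                    len(body) == cfg.nonbohr_protein_length
                    and body[-1] == cfg.nonbohr_cterm_residue
                    and body[cfg.nonbohr_position - 1] == cfg.nonbohr_position_residue
                )
            if not ok:
                raise RuntimeError(f"generator soundness check failed for {rec.name}")
        else:
            defect = rec.defects[0]
            if defect == "no_start" and cds.startswith("ATG"):
                raise RuntimeError(f"planted no_start not manifest in {rec.name}")
            if defect == "missing_exon" and rec.exons[1] is not None:
                raise RuntimeError(f"planted missing_exon not manifest in {rec.name}")
            if defect == "internal_stop" and "*" not in protein[:-1]:
                raise RuntimeError(f"planted internal_stop not manifest in {rec.name}")


def generate_homeolog_pair(
    cfg: SimulationConfig,
    divergence: float,
    ref: GlobinReference | None = None,
) -> tuple[
    tuple[GenomicSequence, list[TruthRecord]],
    tuple[GenomicSequence, list[TruthRecord]],
]:
    """A cluster and an independently diverged copy (duplicated region).

    The copy receives uniform point substitutions at ``divergence`` per
    site, except at rule-critical sites of planted genes, so both truth
    tables remain exact.
    """
    if not 0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    ref = ref if ref is not None else make_templates()
    seq_a, truth_a = generate_cluster(cfg, ref)
    rng = np.random.default_rng(cfg.seed + 7_000_003)

    protected: set[int] = set()
    for rec in truth_a:
        present = [iv for iv in rec.exons if iv is not None]
        if rec.status == "pseudogene":
            # freeze pseudogene exons entirely so planted defects survive
            for s, e in present:
                protected.update(range(s, e))
            continue
        for k, iv in enumerate(rec.exons):
            s, e = iv
            if rec.strand == "+":
                start_nt = range(s, s + 3) if k == 0 else range(0)
                stop_nt = range(e - 3, e) if k == 2 else range(0)
            else:
                start_nt = range(e - 3, e) if k == 0 else range(0)
                stop_nt = range(s, s + 3) if k == 2 else range(0)
            protected.update(start_nt)
            protected.update(stop_nt)
        # splice dinucleotides flank every intron
        if rec.strand == "+":
            for (s1, e1), (s2, e2) in zip(present, present[1:]):
                protected.update(range(e1, e1 + 2))
                protected.update(range(s2 - 2, s2))
        else:
            for (s1, e1), (s2, e2) in zip(present, present[1:]):
                # transcription runs right to left on the forward axis
                protected.update(range(s1 - 2, s1))
                protected.update(range(e2, e2 + 2))

    # hallmark codons of non-Bohr genes, mapped through the spliced CDS
    for rec in truth_a:
        if rec.bohr_status != "non_bohr":
            continue
        targets = {
            3 * (ref.config.nonbohr_position - 1) + k for k in range(3)
        } | {3 * (ref.config.nonbohr_protein_length - 1) + k for k in range(3)}
        cds_pos = 0
        for iv in rec.exons:
            s, e = iv
            for off in range(e - s):
                if cds_pos in targets:
                    g = (s + off) if rec.strand == "+" else (e - 1 - off)
                    protected.add(g)
                cds_pos += 1

    exon_frame: dict[int, tuple[int, str]] = {}
    for rec in truth_a:
        if rec.status != "functional":
            continue
        cds_pos = 0
        for iv in rec.exons:
            s, e = iv
            for off in range(e - s):
                g = (s + off) if rec.strand == "+" else (e - 1 - off)
                exon_frame[g] = (cds_pos, rec.strand)
                cds_pos += 1

    residues = list(seq_a.residues)
    hit = np.flatnonzero(rng.random(len(residues)) < divergence)
    for posn in hit:
        p = int(posn)
        if p in protected:
            continue
        old = residues[p]
        choices = [b for b in _BASES if b != old]
        new = choices[rng.integers(3)]
        residues[p] = new
        if p in exon_frame:
            cds_pos, strand = exon_frame[p]
            # check the affected codon for a newly created stop
            c0 = cds_pos - cds_pos % 3
            inv = _invert_frame(exon_frame, p, c0, strand)
            if inv is not None:
                codon = "".join(
                    residues[g] if strand == "+" else _comp(residues[g]) for g in inv
                )
                if codon in STOP_CODONS:
                    residues[p] = old

    seq_b = GenomicSequence(seq_a.id + "_copy", "".join(residues))
    seq_a = GenomicSequence(seq_a.id + "_orig", seq_a.residues)
    truth_a2 = [replace(r, seq_id=seq_a.id) for r in truth_a]
    truth_b = [replace(r, seq_id=seq_b.id) for r in truth_a]
    return (seq_a, truth_a2), (seq_b, truth_b)


def _comp(base: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[base]


def _invert_frame(
    exon_frame: dict[int, tuple[int, str]], p: int, c0: int, strand: str
) -> list[int] | None:
    """Genomic positions of CDS codon starting at c0, near position p."""
    out = []
    for cp in (c0, c0 + 1, c0 + 2):
        delta = cp - exon_frame[p][0]
        g = p + delta if strand == "+" else p - delta
        if exon_frame.get(g, (None, None))[0] != cp:
            return None  # codon spans a splice junction; skip the check
        out.append(g)
    return out


def generate_lineage_cds(
    seed: int,
    ref: GlobinReference | None = None,
    n_bohr: int = 8,
    n_nonbohr: int = 6,
    divergence: float = 0.02,
) -> list[tuple[str, str]]:
    """CDS set with planted two-lineage clade structure.

    ``n_nonbohr`` sequences descend from the non-Bohr beta template and
    ``n_bohr`` from the Bohr one, each carrying independent background
    substitutions; within-lineage divergence stays well below the
    between-template distance, so the non-Bohr set forms a clade.
    """
    ref = ref if ref is not None else make_templates()
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    for label_base, variant, n in (
        ("bohr", "beta", n_bohr),
        ("nonbohr", "beta_nonbohr", n_nonbohr),
    ):
        cds = ref.cds(variant)
        for k in range(n):
            out.append(
                (f"{label_base}_{k + 1}", _mutate_cds(cds, rng, divergence, set()))
            )
    return out
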