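"""Candidate globin gene discovery in genomic sequence.

Three stages, mirroring how compact multi-copy gene families are
annotated by homology:

1. :func:`find_exon_hits` — translated exon search: each exon template
   peptide is located in the six-frame translation by exact k-mer
   seeding followed by BLOSUM62 local alignment of the seeded windows.
2. :func:`chain_hits` — compatible hits (same strand, same template
   variant, exon indices strictly increasing in transcription order,
   intron-sized gaps) are chained greedily by descending chain score;
   complete 1-2-3 chains become candidate genes, partial chains become
   candidate pseudogene models carrying ``missing_exon``.
3. :func:`refine_model` — exon boundaries are re-anchored at the
   nucleotide level (infix alignment of the template CDS), snapped to
   canonical GT donor / AG acceptor dinucleotides within a small search
   window, the start and stop codons located, and the defect list
   (broken splice sites, lost start/stop, internal stops, frameshifts,
   length violations) recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import AlignmentScoring, local_align, self_score
from .io_formats import GenomicSequence, revcomp
from .reference import STOP_CODONS, GlobinReference, translate

SEED_WORD = 4  # exact peptide k-mer used to seed alignment windows

# defect vocabulary shared with the classifier and the generator
DEFECT_LABELS = (
    "missing_exon",
    "bad_splice_donor",
    "bad_splice_acceptor",
    "internal_stop",
    "frameshift",
    "no_start",
    "no_stop",
    "length_violation",
)


@dataclass(frozen=True)
class FinderConfig:
    """Thresholds for exon search, chaining and refinement."""

    min_identity: float = 0.5
    score_fraction: float = 0.3  # of the template peptide self-score
    intron_min: int = 40
    intron_max: int = 3000
    refine_window: int = 12  # nt search radius for splice/start/stop snapping
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def as_dict(self) -> dict:
        return {
            "min_identity": self.min_identity,
            "score_fraction": self.score_fraction,
            "intron_min": self.intron_min,
            "intron_max": self.intron_max,
            "refine_window": self.refine_window,
            "gap_open": self.scoring.gap_open,
            "gap_extend": self.scoring.gap_extend,
            "matrix": self.scoring.matrix_name,
        }


@dataclass(frozen=True)
class ExonHit:
    """One exon-template match on genomic sequence.

    ``start``/``end`` are forward-strand 0-based half-open; ``ts_start``/
    ``ts_end`` are the same interval on the transcribed strand, and
    ``q_start``/``q_end`` the matched template peptide span.
    """

    seq_id: str
    strand: str
    variant: str
    subunit: str
    exon_index: int
    start: int
    end: int
    score: float
    percent_identity: float
    ts_start: int
    ts_end: int
    q_start: int
    q_end: int


@dataclass
class GeneModel:
    """A located candidate globin gene (possibly defective)."""

    seq_id: str
    strand: str
    subunit: str
    variant: str
    exon_indices: list[int]  # template exon numbers present, ascending
    exons: list[tuple[int, int]]  # forward-strand intervals, transcription order
    hits: list[ExonHit]
    score: float
    defects: list[str] = field(default_factory=list)
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds: str = ""
    protein: str = ""
    splice_ok: list[tuple[bool, bool]] = field(default_factory=list)
    exon_size_ok: list[bool] = field(default_factory=list)
    has_start: bool = False
    has_stop: bool = False
    refined: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def protein_length(self) -> int:
        return len(self.protein.replace("*", ""))

    @property
    def missing_exons(self) -> list[int]:
        return sorted({1, 2, 3} - set(self.exon_indices))


def _add_defect(model: GeneModel, label: str) -> None:
    if label not in model.defects:
        model.defects.append(label)


# ---------------------------------------------------------------------------
# stage 1: translated exon search


def _seed_windows(template_pep: str, index: dict[str, list[int]], prot_len: int):
    """Merged candidate windows (protein coords) from exact k-mer seeds."""
    qlen = len(template_pep)
    diags: list[int] = []
    for qi in range(0, qlen - SEED_WORD + 1):
        word = template_pep[qi : qi + SEED_WORD]
        for tpos in index.get(word, ()):
            diags.append(tpos - qi)
    if not diags:
        return []
    diags.sort()
    windows: list[list[int]] = []
    for d in diags:
        ws, we = d - 3, d + qlen + 3
        if windows and ws <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], we)
        else:
            windows.append([ws, we])
    return [(max(0, ws - 5), min(prot_len, we + 5)) for ws, we in windows]


def find_exon_hits(
    seq: GenomicSequence,
    ref: GlobinReference,
    min_identity: float | None = None,
    config: FinderConfig | None = None,
) -> list[ExonHit]:
    """Scan both strands for exon-template matches.

    A window is reported when its local-alignment identity reaches
    ``min_identity`` and its score reaches ``score_fraction`` times the
    template's self-score.  An empty list is a legal result.
    """
    config = config or FinderConfig()
    if min_identity is None:
        min_identity = config.min_identity
    L = len(seq)
    hits: list[ExonHit] = []
    thresholds = {
        (v, i): config.score_fraction * self_score(ref.exon(v, i).peptide, config.scoring)
        for v in ref.variants
        for i in (1, 2, 3)
    }
    for strand in "+-":
        ts = seq.residues if strand == "+" else revcomp(seq.residues)
        for frame in (0, 1, 2):
            prot = translate(ts, phase=frame)
            index: dict[str, list[int]] = {}
            for p in range(0, len(prot) - SEED_WORD + 1):
                index.setdefault(prot[p : p + SEED_WORD], []).append(p)
            for variant in ref.variants:
                for exon_index in (1, 2, 3):
                    tpl = ref.exon(variant, exon_index)
                    for ws, we in _seed_windows(tpl.peptide, index, len(prot)):
                        window = prot[ws:we]
                        if not window:
                            continue
                        aln = local_align(tpl.peptide, window, config.scoring)
                        if aln.n_columns == 0:
                            continue
                        if aln.score < thresholds[(variant, exon_index)]:
                            continue
                        if aln.identity < min_identity:
                            continue
                        p_s, p_e = ws + aln.b_span[0], ws + aln.b_span[1]
                        nt_s, nt_e = frame + 3 * p_s, frame + 3 * p_e
                        if strand == "+":
                            f_s, f_e = nt_s, nt_e
                        else:
                            f_s, f_e = L - nt_e, L - nt_s
                        hits.append(
                            ExonHit(
                                seq_id=seq.id,
                                strand=strand,
                                variant=variant,
                                subunit=ref.subunit_of(variant),
                                exon_index=exon_index,
                                start=f_s,
                                end=f_e,
                                score=aln.score,
                                percent_identity=aln.identity,
                                ts_start=nt_s,
                                ts_end=nt_e,
                                q_start=aln.a_span[0],
                                q_end=aln.a_span[1],
                            )
                        )
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: (h.seq_id, h.start, h.end, h.strand, h.variant, h.exon_index))
    return hits


def _dedupe_hits(hits: list[ExonHit]) -> list[ExonHit]:
    """Collapse same-exon hits whose intervals largely overlap (keep best)."""
    kept: list[ExonHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.strand, h.variant, h.exon_index)):
        redundant = False
        for k in kept:
            if (
                k.strand == h.strand
                and k.variant == h.variant
                and k.exon_index == h.exon_index
            ):
                ov = min(k.ts_end, h.ts_end) - max(k.ts_start, h.ts_start)
                if ov > 0.5 * min(k.ts_end - k.ts_start, h.ts_end - h.ts_start):
                    redundant = True
                    break
        if not redundant:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# stage 2: chaining


def chain_hits(hits: list[ExonHit], config: FinderConfig | None = None) -> list[GeneModel]:
    """Assemble exon hits into candidate gene models.

    Greedy extraction of maximal-scoring compatible chains; each hit is
    assigned to at most one model.  Ties are broken toward smaller total
    intron length, then toward the leftmost chain on the transcribed
    strand.
    """
    config = config or FinderConfig()
    models: list[GeneModel] = []
    groups: dict[tuple[str, str, str], list[ExonHit]] = {}
    for h in hits:
        groups.setdefault((h.seq_id, h.strand, h.variant), []).append(h)
    for key in sorted(groups):
        pool = sorted(groups[key], key=lambda h: (h.ts_start, h.exon_index))
        while pool:
            chain = _best_chain(pool, config)
            if not chain:
                break
            models.append(_model_from_chain(chain))
            chosen = set(id(h) for h in chain)
            pool = [h for h in pool if id(h) not in chosen]
    models.sort(key=lambda m: (m.seq_id, m.start, m.strand, m.variant))
    return models


def _best_chain(pool: list[ExonHit], config: FinderConfig) -> list[ExonHit]:
    n = len(pool)
    if n == 0:
        return []
    score = [h.score for h in pool]
    gap_total = [0] * n
    back = [-1] * n
    for i in range(n):
        for j in range(i):
            if pool[j].exon_index >= pool[i].exon_index:
                continue
            gap = pool[i].ts_start - pool[j].ts_end
            if not (config.intron_min <= gap <= config.intron_max):
                continue
            cand = (score[j] + pool[i].score, -(gap_total[j] + gap))
            if cand > (score[i], -gap_total[i]):
                score[i] = cand[0]
                gap_total[i] = -cand[1]
                back[i] = j
    best_i = max(
        range(n), key=lambda i: (score[i], -gap_total[i], -pool[i].ts_start)
    )
    chain: list[ExonHit] = []
    i = best_i
    while i != -1:
        chain.append(pool[i])
        i = back[i]
    chain.reverse()
    return chain


def _model_from_chain(chain: list[ExonHit]) -> GeneModel:
    h0 = chain[0]
    model = GeneModel(
        seq_id=h0.seq_id,
        strand=h0.strand,
        subunit=h0.subunit,
        variant=h0.variant,
        exon_indices=[h.exon_index for h in chain],
        exons=[(h.start, h.end) for h in chain],
        hits=list(chain),
        score=sum(h.score for h in chain),
    )
    if model.missing_exons:
        model.defects.append("missing_exon")
    return model


# ---------------------------------------------------------------------------
# stage 3: refinement


def _head_fitness(obs_pep: str, tpl_pep: str, k: int = 8) -> int:
    k = min(k, len(obs_pep), len(tpl_pep))
    return sum(obs_pep[i] == tpl_pep[i] for i in range(k))


def _matches(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def _polish_start(ts: str, tpl_cds: str, est: int, radius: int = 3) -> int:
    """Exact 5' boundary: best match of the template's first 12 nt.

    Infix-alignment endpoints can drift a base or two when terminal
    template positions are diverged; maximizing the exact nucleotide
    match of the boundary-proximal template segment removes that
    jitter, which the strict GT/AG checks below rely on.
    """
    k = min(12, len(tpl_cds))
    cands = [s for s in range(max(0, est - radius), est + radius + 1) if s + k <= len(ts)]
    if not cands:
        return est
    return min(
        cands,
        key=lambda s: (-_matches(tpl_cds[:k], ts[s : s + k]), abs(s - est), s),
    )


def _polish_end(ts: str, tpl_cds: str, est: int, radius: int = 3) -> int:
    """Exact 3' boundary: best match of the template's last 12 nt."""
    k = min(12, len(tpl_cds))
    cands = [e for e in range(max(k, est - radius), min(len(ts), est + radius) + 1)]
    if not cands:
        return est
    return min(
        cands,
        key=lambda e: (-_matches(tpl_cds[-k:], ts[e - k : e]), abs(e - est), e),
    )


def _anchor_exon(ts: str, tpl_cds: str, proj_start: int, pad: int = 30) -> tuple[int, int]:
    """Nucleotide-homology estimate of an exon interval (infix alignment)."""
    win_s = max(0, proj_start - pad)
    win_e = min(len(ts), proj_start + len(tpl_cds) + pad)
    if win_e - win_s < 8:
        return proj_start, proj_start + len(tpl_cds)
    res = edlib.align(tpl_cds, ts[win_s:win_e], mode="HW", task="locations")
    locs = res.get("locations") or []
    if not locs or locs[0][0] is None:
        return proj_start, proj_start + len(tpl_cds)
    s, e = locs[0]
    return win_s + s, win_s + e + 1


def refine_model(
    model: GeneModel,
    seq: GenomicSequence,
    ref: GlobinReference,
    config: FinderConfig | None = None,
) -> GeneModel:
    """Fix exon boundaries on splice signals and recompute defects."""
    config = config or FinderConfig()
    w = config.refine_window
    L = len(seq)
    ts = seq.residues if model.strand == "+" else revcomp(seq.residues)
    templates = ref.templates[model.variant]
    present = model.exon_indices
    hits_by_index = {h.exon_index: h for h in model.hits}

    est: dict[int, tuple[int, int]] = {}
    for idx in present:
        h = hits_by_index[idx]
        proj = h.ts_start - 3 * h.q_start
        est[idx] = _anchor_exon(ts, templates[idx].cds, proj)

    starts: dict[int, int] = {}
    ends: dict[int, int] = {}
    splice_ok: list[tuple[bool, bool]] = []

    # 5' boundary of the first present exon
    first = present[0]
    start_f = _polish_start(ts, templates[first].cds, est[first][0])
    if first == 1:
        if ts[start_f : start_f + 3] != "ATG":
            # tolerate a start a codon or two away if it continues in frame
            tpl_pep = templates[1].peptide
            for delta in (-3, 3, -6, 6):
                p = start_f + delta
                if (
                    0 <= p
                    and ts[p : p + 3] == "ATG"
                    and _head_fitness(translate(ts[p : p + 24]), tpl_pep) >= 6
                ):
                    start_f = p
                    break
    starts[first] = start_f

    # junctions between consecutive present exons: the splice sites of a
    # sound gene sit exactly at the template-homologous boundaries
    for i_idx, j_idx in zip(present, present[1:]):
        donor = _polish_end(ts, templates[i_idx].cds, est[i_idx][1])
        donor = max(donor, starts[i_idx] + 3)
        donor_ok = ts[donor : donor + 2] == "GT"
        if not donor_ok:
            _add_defect(model, "bad_splice_donor")
        ends[i_idx] = donor

        acceptor = _polish_start(ts, templates[j_idx].cds, est[j_idx][0])
        acceptor = max(acceptor, donor + 4)
        acceptor_ok = ts[acceptor - 2 : acceptor] == "AG"
        if not acceptor_ok:
            _add_defect(model, "bad_splice_acceptor")
        starts[j_idx] = acceptor
        splice_ok.append((donor_ok, acceptor_ok))

    # 3' boundary of the last present exon
    last = present[-1]
    tpl_last = templates[last].cds
    if last == 3:
        s3 = starts[3]
        m0 = len(tpl_last) // 3
        radius = max(1, w // 3)
        stop_m = None
        for m in sorted(
            range(max(1, m0 - radius), m0 + radius + 1), key=lambda m: (abs(m - m0), m)
        ):
            codon = ts[s3 + 3 * m : s3 + 3 * m + 3]
            if codon in STOP_CODONS:
                stop_m = m
                break
        if stop_m is not None:
            ends[3] = s3 + 3 * stop_m + 3
            model.has_stop = True
        else:
            ends[3] = min(len(ts), s3 + len(tpl_last))
            model.has_stop = False
    else:
        ends[last] = max(
            _polish_end(ts, tpl_last, est[last][1]), starts[last] + 3
        )
        model.has_stop = False
    if not model.has_stop:
        _add_defect(model, "no_stop")

    # assemble spliced CDS and translation
    cds_parts = [ts[starts[i] : ends[i]] for i in present]
    model.cds = "".join(cds_parts)
    model.has_start = (1 in present) and model.cds.startswith("ATG")
    if not model.has_start:
        _add_defect(model, "no_start")
    protein = translate(model.cds)
    if model.has_stop and protein.endswith("*"):
        protein = protein[:-1]
    model.protein = protein
    if "*" in protein:
        _add_defect(model, "internal_stop")

    # frameshift and exon-size checks
    model.exon_size_ok = []
    for idx in present:
        obs = ends[idx] - starts[idx]
        if idx == 3 and model.has_stop:
            obs -= 3
        tpl_len = len(templates[idx].cds)
        if (obs - tpl_len) % 3 != 0:
            _add_defect(model, "frameshift")
        lo, hi = templates[idx].expected_peptide_length_range
        model.exon_size_ok.append(lo <= obs // 3 <= hi)

    expected = ref.config.expected_protein_lengths(model.subunit)
    if model.protein_length not in expected:
        _add_defect(model, "length_violation")

    # final intervals (forward-strand coordinates, transcription order)
    def to_forward(iv: tuple[int, int]) -> tuple[int, int]:
        return iv if model.strand == "+" else (L - iv[1], L - iv[0])

    model.exons = [to_forward((starts[i], ends[i])) for i in present]
    model.intron_intervals = [
        to_forward((ends[i], starts[j])) for i, j in zip(present, present[1:])
    ]
    model.splice_ok = splice_ok
    model.defects = sorted(set(model.defects), key=DEFECT_LABELS.index)
    model.refined = True
    return model


# ---------------------------------------------------------------------------
# orchestration


def find_genes(
    seq: GenomicSequence,
    ref: GlobinReference,
    config: FinderConfig | None = None,
) -> list[GeneModel]:
    """Full finder: search, chain, resolve overlaps, refine.

    Overlapping same-strand models (alternative template variants or
    leftover fragments of an already-explained locus) are resolved by
    keeping the highest-scoring model per locus.
    """
    config = config or FinderConfig()
    hits = find_exon_hits(seq, ref, config=config)
    models = chain_hits(hits, config)
    models.sort(key=lambda m: (-m.score, m.start, m.strand, m.variant))
    accepted: list[GeneModel] = []
    for m in models:
        s, e = m.span
        clash = any(
            a.strand == m.strand and s < a.span[1] and a.span[0] < e
            for a in accepted
        )
        if not clash:
            accepted.append(m)
    for m in accepted:
        refine_model(m, seq, ref, config)
    accepted.sort(key=lambda m: (m.seq_id, m.start))
    return accepted
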