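"""Flanking-gene synteny typing and sequence-level homeology checks.

Teleost hemoglobin clusters come in two ancestral types distinguished
by their neighbours: Cluster 1 (UPF0171 protein C16orf35, Rhomboid
family member 1, Dedicator of cytokinesis protein 6, ELAV-like protein
3, DNA-3-methyladenine glycosylase) and Cluster 2 (Aquaporin-8,
Rho-GTPase-activating protein).  A cluster is typed by which signature
set its flanking genes hit more often; ties (including no hits) are
ambiguous.  Sequence-level homeology between duplicated cluster copies
is assessed with an exact-word dot plot and windowed identity along an
anchored alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .io_formats import FormatError, GenomicSequence, revcomp


def canonical_name(name: str) -> str:
    """Case-fold and strip punctuation for gene-name comparison."""
    key = re.sub(r"[^a-z0-9]", "", name.casefold())
    return _SYNONYMS.get(key, key)


# small synonym table standing in for database identifier mapping
_SYNONYMS = {
    "mpg": "dna3methyladenineglycosylase",
    "c16orf35": "upf0171proteinc16orf35",
    "upf0171": "upf0171proteinc16orf35",
    "dock6": "dedicatorofcytokinesisprotein6",
    "elavl3": "elavlikeprotein3",
    "elavlikeprotein3": "elavlikeprotein3",
    "rhbdf1": "rhomboidfamilymember1",
    "rhomboid5homolog1": "rhomboidfamilymember1",
    "aqp8": "aquaporin8",
    "arhgap": "rhogtpaseactivatingprotein",
}


@dataclass
class FlankingGeneSet:
    """Named genes flanking one hemoglobin cluster in one species."""

    species: str
    cluster_id: str
    genes: list[tuple[str, str]]  # (name, orientation: toward|away|unknown)

    @property
    def canonical_genes(self) -> list[str]:
        seen: list[str] = []
        for name, _ in self.genes:
            c = canonical_name(name)
            if c not in seen:
                seen.append(c)
        return seen


@dataclass(frozen=True)
class SignatureSets:
    cluster1: frozenset[str] = frozenset(
        {
            "UPF0171 protein C16orf35",
            "Rhomboid family member 1",
            "Dedicator of cytokinesis protein 6",
            "ELAV-like protein 3",
            "DNA-3-methyladenine glycosylase",
        }
    )
    cluster2: frozenset[str] = frozenset(
        {"Aquaporin-8", "Rho-GTPase-activating protein"}
    )

    def __post_init__(self) -> None:
        c1 = {canonical_name(g) for g in self.cluster1}
        c2 = {canonical_name(g) for g in self.cluster2}
        if c1 & c2:
            raise ValueError("signature sets must be disjoint")


@dataclass
class ClusterTypeResult:
    label: str  # cluster1 | cluster2 | ambiguous
    cluster1_hits: list[str] = field(default_factory=list)
    cluster2_hits: list[str] = field(default_factory=list)


def classify_cluster(
    flank: FlankingGeneSet, sig: SignatureSets | None = None
) -> ClusterTypeResult:
    """Type a cluster by signature-gene presence (order/duplicates ignored)."""
    sig = sig or SignatureSets()
    c1 = {canonical_name(g): g for g in sorted(sig.cluster1)}
    c2 = {canonical_name(g): g for g in sorted(sig.cluster2)}
    present = set(flank.canonical_genes)
    hits1 = sorted(c1[k] for k in present & set(c1))
    hits2 = sorted(c2[k] for k in present & set(c2))
    if len(hits1) > len(hits2):
        label = "cluster1"
    elif len(hits2) > len(hits1):
        label = "cluster2"
    else:
        label = "ambiguous"
    return ClusterTypeResult(label, hits1, hits2)


def shared_gene_matrix(flanks: list[FlankingGeneSet]) -> pd.DataFrame:
    """Presence/absence matrix of canonical gene names across flanks.

    Rows are gene names in first-seen order; columns are
    ``species|cluster_id``.
    """
    if len(flanks) < 2:
        raise ValueError("shared_gene_matrix needs at least two flank sets")
    row_order: list[str] = []
    for f in flanks:
        for g in f.canonical_genes:
            if g not in row_order:
                row_order.append(g)
    data = {
        f"{f.species}|{f.cluster_id}": [g in set(f.canonical_genes) for g in row_order]
        for f in flanks
    }
    return pd.DataFrame(data, index=row_order)


def read_flank_tsv(path: str | Path) -> list[FlankingGeneSet]:
    """Read flank TSV (species, cluster_id, gene_name, orientation)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    required = {"species", "cluster_id", "gene_name"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"flank table missing column(s) {sorted(missing)}")
    if "orientation" not in df.columns:
        df["orientation"] = "unknown"
    flanks = []
    for (species, cluster_id), grp in df.groupby(["species", "cluster_id"], sort=False):
        flanks.append(
            FlankingGeneSet(
                species=species,
                cluster_id=cluster_id,
                genes=list(zip(grp["gene_name"], grp["orientation"])),
            )
        )
    return flanks


# ---------------------------------------------------------------------------
# dot plot and windowed identity


@dataclass
class DotPlot:
    """Exact word matches between two sequences, by strand channel."""

    shape: tuple[int, int]
    word: int
    forward: list[tuple[int, int]] = field(default_factory=list)
    reverse: list[tuple[int, int]] = field(default_factory=list)

    def transpose(self) -> "DotPlot":
        return DotPlot(
            shape=(self.shape[1], self.shape[0]),
            word=self.word,
            forward=sorted((j, i) for i, j in self.forward),
            reverse=sorted((j, i) for i, j in self.reverse),
        )


def dotplot(
    a: GenomicSequence, b: GenomicSequence, word: int = 15, step: int = 1
) -> DotPlot:
    """Exact-word match matrix; forward and reverse-complement channels.

    A reverse hit (i, j) marks word ``a[i:i+word]`` equal to the
    reverse complement of ``b[j:j+word]``.
    """
    if word < 8:
        raise ValueError("word must be >= 8")
    dp = DotPlot(shape=(len(a), len(b)), word=word)
    if len(a) < word or len(b) < word:
        return dp
    index: dict[str, list[int]] = {}
    for j in range(0, len(b) - word + 1, step):
        index.setdefault(b.residues[j : j + word], []).append(j)
    for i in range(0, len(a) - word + 1, step):
        w = a.residues[i : i + word]
        for j in index.get(w, ()):
            dp.forward.append((i, j))
        for j in index.get(revcomp(w), ()):
            dp.reverse.append((i, j))
    dp.forward.sort()
    dp.reverse.sort()
    return dp


def _collinear_anchors(a: str, b: str, word: int) -> list[tuple[int, int]]:
    """Unique-in-both exact word matches, chained to a collinear subset."""
    index_b: dict[str, int | None] = {}
    for j in range(len(b) - word + 1):
        w = b[j : j + word]
        index_b[w] = j if w not in index_b else None
    seen_a: dict[str, int | None] = {}
    for i in range(len(a) - word + 1):
        w = a[i : i + word]
        seen_a[w] = i if w not in seen_a else None
    pairs = sorted(
        (i, index_b[w])
        for w, i in seen_a.items()
        if i is not None and index_b.get(w) is not None
    )
    # longest chain with both coordinates strictly increasing (patience LIS)
    import bisect

    tails: list[int] = []
    tail_idx: list[int] = []
    back = [-1] * len(pairs)
    for k, (_, j) in enumerate(pairs):
        pos = bisect.bisect_left(tails, j)
        if pos == len(tails):
            tails.append(j)
            tail_idx.append(k)
        else:
            tails[pos] = j
            tail_idx[pos] = k
        back[k] = tail_idx[pos - 1] if pos > 0 else -1
    chain: list[tuple[int, int]] = []
    if tail_idx:
        k = tail_idx[-1]
        while k != -1:
            chain.append(pairs[k])
            k = back[k]
        chain.reverse()
    # drop anchors that overlap their predecessor
    filtered: list[tuple[int, int]] = []
    for i, j in chain:
        if not filtered or (i >= filtered[-1][0] + word and j >= filtered[-1][1] + word):
            filtered.append((i, j))
    return filtered


def _segment_match_flags(a_seg: str, b_seg: str) -> np.ndarray:
    """Per-position match flags for a (global edlib alignment)."""
    flags = np.zeros(len(a_seg), dtype=bool)
    if not a_seg:
        return flags
    if not b_seg:
        return flags
    if a_seg == b_seg:
        flags[:] = True
        return flags
    res = edlib.align(a_seg, b_seg, mode="NW", task="path")
    cigar = res["cigar"] or ""
    ai = 0
    for length, op in re.findall(r"(\d+)([=XID])", cigar):
        n = int(length)
        if op == "=":
            flags[ai : ai + n] = True
            ai += n
        elif op in ("X", "I"):  # I consumes the first sequence only
            ai += n
        # 'D' consumes the second sequence only
    return flags


def windowed_identity(
    a: GenomicSequence,
    b: GenomicSequence,
    window: int = 1000,
    word: int = 15,
) -> list[tuple[int, float]]:
    """Identity of b to a in non-overlapping windows along a.

    Collinear unique-word anchors are chained, the inter-anchor
    segments aligned globally, and per-position match flags aggregated
    over windows of ``window`` bp of sequence ``a``.
    """
    flags = np.zeros(len(a), dtype=bool)
    anchors = _collinear_anchors(a.residues, b.residues, word)
    if not anchors:
        flags = _segment_match_flags(a.residues, b.residues)
    else:
        pa = pb = 0
        for ai, bj in anchors + [(len(a), len(b))]:
            flags[pa:ai] = _segment_match_flags(a.residues[pa:ai], b.residues[pb:bj])
            if ai < len(a):
                flags[ai : ai + word] = True
                pa, pb = ai + word, bj + word
    out: list[tuple[int, float]] = []
    size = min(window, len(a))
    if size == 0:
        return out
    for start in range(0, len(a) - size + 1, size):
        out.append((start, float(flags[start : start + size].mean())))
    return out


def render_dotplot(dp: DotPlot, path: str | Path, title: str = "") -> None:
    """Scatter rendering of a dot plot (forward black, reverse red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if dp.forward:
        xs, ys = zip(*dp.forward)
        ax.plot(xs, ys, ".", color="black", markersize=1, label="forward")
    if dp.reverse:
        xs, ys = zip(*dp.reverse)
        ax.plot(xs, ys, ".", color="red", markersize=1, label="reverse")
    ax.set_xlabel("sequence A (bp)")
    ax.set_ylabel("sequence B (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
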