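"""Local alignment engine used by the exon search.

Thin, deterministic wrapper around Bio.Align.PairwiseAligner in local
mode with BLOSUM62 substitution scores and affine gap penalties: a gap
of length L costs ``gap_open + L * gap_extend`` (BLAST-style 11/1 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices


@dataclass(frozen=True)
class AlignmentScoring:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    a_span: tuple[int, int]  # aligned interval in a (half-open)
    b_span: tuple[int, int]  # aligned interval in b (half-open)
    identity: float  # identities / aligned columns, in [0, 1]
    n_columns: int


@lru_cache(maxsize=8)
def _aligner(scoring: AlignmentScoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix_name)
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def self_score(a: str, scoring: AlignmentScoring | None = None) -> float:
    """Score of a residue string aligned to itself (no gaps)."""
    scoring = scoring or AlignmentScoring()
    matrix = _aligner(scoring).substitution_matrix
    return float(sum(matrix[c, c] for c in a))


def local_align(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> LocalAlignment:
    """Optimal local alignment of residue strings ``a`` and ``b``.

    Returns the optimal score together with the aligned intervals and
    identity of the aligner's first (canonical) optimal path.  A pair
    with no positively scoring alignment yields score 0 and empty spans.
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty inputs")
    scoring = scoring or AlignmentScoring()
    aligner = _aligner(scoring)
    score = float(aligner.score(a, b))
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), 0.0, 0)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    blocks_a, blocks_b = aln.aligned
    a_span = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    b_span = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    identity = counts.identities / columns if columns else 0.0
    return LocalAlignment(score, a_span, b_span, identity, int(columns))
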