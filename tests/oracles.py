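"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by a different algorithm than the
implementation under test: exhaustive dynamic programming for local
alignment and edit distance, and a Steiner-subtree argument for
monophyly.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_affine_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Exhaustive affine-gap Smith-Waterman; a gap of length L costs
    gap_open + L * gap_extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend
            )
            F[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend
            )
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def levenshtein(a: str, b: str) -> int:
    """Plain quadratic edit-distance DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def bipartition_monophyly(tree, subset: set[str]) -> bool:
    """Monophyly by exhaustive edge removal: some edge must split the
    leaves into exactly the subset and its complement."""
    import networkx as nx

    leaves = set(tree.leaves)
    subset = {str(s) for s in subset}
    if subset == leaves:
        return True
    g = nx.Graph()
    for u, v, _ in tree.edges():
        g.add_edge(u, v)
    for u, v, _ in tree.edges():
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        g.add_edge(u, v)
        if (comp & leaves) == subset or (leaves - comp) == subset:
            return True
    return False


def enumerate_chains(hits, intron_min: int, intron_max: int):
    """All compatible hit chains (brute force over subsets, tiny inputs)."""
    import itertools

    chains = []
    order = sorted(range(len(hits)), key=lambda i: hits[i].ts_start)
    for r in range(1, len(hits) + 1):
        for combo in itertools.combinations(order, r):
            hs = [hits[i] for i in combo]
            ok = all(
                h1.exon_index < h2.exon_index
                and intron_min <= h2.ts_start - h1.ts_end <= intron_max
                and h1.strand == h2.strand
                and h1.variant == h2.variant
                for h1, h2 in zip(hs, hs[1:])
            )
            if ok:
                chains.append(hs)
    return chains
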