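"""Distance-based phylogenetics: neighbor joining and monophyly tests.

Used to check clade-level claims about the globin repertoire — e.g.
that the non-Bohr beta genes form a distinct clade — without Bayesian
machinery.  Distances are normalized edit distances between coding
sequences; trees are built with canonical neighbor joining; monophyly
of a leaf subset on an unrooted tree means some edge bipartitions the
leaves into exactly that subset and its complement.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def pairwise_distances(cds_set: list[tuple[str, str]]) -> DistanceMatrix:
    """Normalized edit distance (Levenshtein / max length) between CDS.

    For equal-length gap-free pairs this is exactly the fraction of
    differing positions.
    """
    if len(cds_set) < 3:
        raise ValueError("pairwise_distances needs at least 3 sequences")
    labels = [label for label, _ in cds_set]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(cds_set)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = cds_set[i][1], cds_set[j][1]
        dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        d[i, j] = d[j, i] = dist / max(len(a), len(b))
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class Tree:
    """Unrooted tree as an adjacency map with branch lengths."""

    adjacency: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    leaves: list[str] = field(default_factory=list)

    def add_edge(self, u: str, v: str, length: float) -> None:
        self.adjacency.setdefault(u, []).append((v, length))
        self.adjacency.setdefault(v, []).append((u, length))

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u in sorted(self.adjacency):
            for v, w in self.adjacency[u]:
                if u < v:
                    out.append((u, v, w))
        return out

    def _side_leaves(self, u: str, v: str) -> frozenset[str]:
        """Leaves on the v side of edge (u, v)."""
        seen = {u, v}
        stack = [v]
        found = set()
        while stack:
            node = stack.pop()
            if node in self.leaf_set:
                found.add(node)
            for nbr, _ in self.adjacency[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(found)

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaves)

    def bipartitions(self) -> list[tuple[tuple[str, str], frozenset[str]]]:
        """Every edge with the leaf set on its second-node side."""
        return [((u, v), self._side_leaves(u, v)) for u, v, _ in self.edges()]

    def nontrivial_splits(self) -> set[frozenset[str]]:
        """Internal-edge splits, each as the smaller-side leaf set frozen
        against complementation (canonical min side by sorted labels)."""
        out = set()
        all_leaves = self.leaf_set
        for _, side in self.bipartitions():
            if 1 < len(side) < len(all_leaves) - 1:
                comp = all_leaves - side
                out.add(min(side, comp, key=lambda s: sorted(s)))
        return out

    def is_monophyletic(self, label_subset: set[str]) -> tuple[bool, tuple[str, str] | None]:
        """True iff some edge bipartitions the leaves into exactly
        ``label_subset`` and the rest; returns that edge when true."""
        subset = frozenset(label_subset)
        unknown = subset - self.leaf_set
        if unknown:
            raise KeyError(f"unknown label(s): {sorted(unknown)}")
        all_leaves = self.leaf_set
        if subset == all_leaves:
            # trivially one side of any pendant edge's complement
            return True, self.edges()[0][:2]
        for (u, v), side in self.bipartitions():
            if side == subset or (all_leaves - side) == subset:
                return True, (u, v)
        return False, None

    def newick(self) -> str:
        """Newick string rooted arbitrarily at the highest-degree node."""
        root = max(sorted(self.adjacency), key=lambda n: len(self.adjacency[n]))

        def render(node: str, parent: str | None) -> str:
            children = [
                (nbr, w) for nbr, w in self.adjacency[node] if nbr != parent
            ]
            if not children:
                return node
            inner = ",".join(f"{render(n, node)}:{w:.6f}" for n, w in children)
            label = node if node in self.leaf_set else ""
            return f"({inner}){label}"

        return render(root, None) + ";"


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Canonical neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q-criterion is joined; ties go to the
    lexicographically smallest label pair (labels of the current
    nodes).  Negative branch lengths are clamped to zero with a
    warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = Tree(leaves=list(dm.labels))
    active = list(dm.labels)
    d = {
        (a, b): dm.d[i, j]
        for i, a in enumerate(dm.labels)
        for j, b in enumerate(dm.labels)
    }
    counter = itertools.count(1)

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=2)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * d[(a, b)] - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        new = f"_nj{next(counter)}"
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[(a, b)] - la
        tree.add_edge(new, a, clamp(la))
        tree.add_edge(new, b, clamp(lb))
        for c in active:
            if c in (a, b):
                continue
            dv = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(new, c)] = d[(c, new)] = max(dv, 0.0)
        d[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]

    a, b, c = sorted(active)
    center = f"_nj{next(counter)}"
    tree.add_edge(center, a, clamp(0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])))
    tree.add_edge(center, b, clamp(0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])))
    tree.add_edge(center, c, clamp(0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])))
    return tree


def is_monophyletic(tree: Tree, label_subset: set[str]) -> tuple[bool, tuple[str, str] | None]:
    """Module-level convenience wrapper around :meth:`Tree.is_monophyletic`."""
    return tree.is_monophyletic(label_subset)


# ---------------------------------------------------------------------------
# simulation helpers (additive matrices with known topology)


def random_additive_matrix(
    n_taxa: int, rng: np.random.Generator
) -> tuple[DistanceMatrix, set[frozenset[str]]]:
    """A distance matrix that is exactly additive on a random binary tree.

    Returns the matrix and the generating tree's nontrivial splits, for
    checking that reconstruction recovers the topology.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = [f"t{i}" for i in range(n_taxa)]
    tree = Tree(leaves=list(labels))
    nodes = list(labels)
    counter = itertools.count(1)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        new = f"_g{next(counter)}"
        tree.add_edge(new, a, float(rng.uniform(0.05, 1.0)))
        tree.add_edge(new, b, float(rng.uniform(0.05, 1.0)))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]
    center = f"_g{next(counter)}"
    for x in nodes:
        tree.add_edge(center, x, float(rng.uniform(0.05, 1.0)))

    # path distances between leaves
    index = {lab: i for i, lab in enumerate(labels)}
    d = np.zeros((n_taxa, n_taxa))
    for leaf in labels:
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nbr, w in tree.adjacency[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for other in labels:
            d[index[leaf], index[other]] = dist[other]
    return DistanceMatrix(labels, d), tree.nontrivial_splits()
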