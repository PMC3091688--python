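import numpy as np
import pytest

from hbcluster.phylo import (
    DistanceMatrix,
    is_monophyletic,
    neighbor_joining,
    pairwise_distances,
    random_additive_matrix,
)
from hbcluster.simulate import generate_lineage_cds

from .oracles import levenshtein, bipartition_monophyly


class TestPairwiseDistances:
    def test_identical_pair_distance_zero(self):
        dm = pairwise_distances([("a", "ACGT" * 30), ("b", "ACGT" * 30), ("c", "TTTT" * 30)])
        assert dm.d[0, 1] == 0.0

    def test_five_mismatches_in_100_is_005(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = list(a)
        for i in (3, 20, 45, 60, 99):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        dm = pairwise_distances([("a", a), ("b", "".join(b)), ("c", a[::-1])])
        assert dm.d[0, 1] == pytest.approx(0.05)

    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances([("a", "ACGT"), ("b", "ACGT")])

    def test_random_sets_agree_with_dp_oracle(self):
        rng = np.random.default_rng(2)
        seqs = [
            (f"s{i}", "".join(rng.choice(list("ACGT"), size=int(rng.integers(30, 80)))))
            for i in range(5)
        ]
        dm = pairwise_distances(seqs)
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = seqs[i][1], seqs[j][1]
                assert dm.d[i, j] == pytest.approx(
                    levenshtein(a, b) / max(len(a), len(b))
                )


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]]))
        tree = neighbor_joining(dm)
        lengths = {tuple(sorted((u, v))): w for u, v, w in tree.edges()}
        center = next(n for n in tree.adjacency if n.startswith("_nj"))
        assert lengths[tuple(sorted((center, "a")))] == pytest.approx(1.0)
        assert lengths[tuple(sorted((center, "b")))] == pytest.approx(2.0)
        assert lengths[tuple(sorted((center, "c")))] == pytest.approx(3.0)

    def test_additive_five_taxon_matrix_recovers_topology(self):
        rng = np.random.default_rng(3)
        dm, splits = random_additive_matrix(5, rng)
        assert neighbor_joining(dm).nontrivial_splits() == splits

    def test_ultrametric_four_taxon_split(self):
        # (a,b) vs (c,d) with clean structure
        d = np.array(
            [[0, 0.2, 1.0, 1.0], [0.2, 0, 1.0, 1.0], [1.0, 1.0, 0, 0.2], [1.0, 1.0, 0.2, 0]]
        )
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c", "d"], d))
        assert tree.nontrivial_splits() == {frozenset({"a", "b"})}

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))

    def test_negative_branch_lengths_clamped_with_warning(self):
        d = np.array([[0, 0.1, 0.2], [0.1, 0, 0.4], [0.2, 0.4, 0]])
        with pytest.warns(UserWarning, match="clamped"):
            tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        assert all(w >= 0 for _, _, w in tree.edges())

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        dm, _ = random_additive_matrix(8, rng)
        noisy = dm.d + rng.uniform(0, 0.01, size=dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        ours = neighbor_joining(DistanceMatrix(dm.labels, noisy)).nontrivial_splits()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=dm.labels))
        theirs = set()
        all_leaves = frozenset(dm.labels)
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_leaves) - 1:
                comp = all_leaves - side
                theirs.add(min(side, comp, key=lambda s: sorted(s)))
        assert ours == theirs


class TestMonophyly:
    def _tree(self, n=6, seed=5):
        dm, _ = random_additive_matrix(n, np.random.default_rng(seed))
        return neighbor_joining(dm)

    def test_full_leaf_set_is_trivially_monophyletic(self):
        tree = self._tree()
        ok, edge = tree.is_monophyletic(set(tree.leaves))
        assert ok and edge is not None

    def test_singleton_is_monophyletic(self):
        tree = self._tree()
        ok, _ = is_monophyletic(tree, {tree.leaves[0]})
        assert ok

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            self._tree().is_monophyletic({"nope"})

    def test_agrees_with_exhaustive_bipartition_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(25):
            n = int(rng.integers(4, 11))
            dm, _ = random_additive_matrix(n, rng)
            tree = neighbor_joining(dm)
            k = int(rng.integers(2, n))
            subset = set(rng.choice(dm.labels, size=k, replace=False))
            assert tree.is_monophyletic(subset)[0] == bipartition_monophyly(tree, subset)

    def test_planted_nonbohr_lineage_forms_a_clade(self, templates):
        cds = generate_lineage_cds(17, templates)
        tree = neighbor_joining(pairwise_distances(cds))
        nonbohr = {label for label, _ in cds if label.startswith("nonbohr")}
        ok, edge = tree.is_monophyletic(nonbohr)
        assert ok and edge is not None

    def test_newick_round_trips_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        tree = self._tree(7)
        dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.taxon.label for t in dt.leaf_node_iter()} == set(tree.leaves)
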