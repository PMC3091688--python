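import numpy as np
import pytest

from hbcluster.io_formats import GenomicSequence, revcomp
from hbcluster.simulate import chr6_config, generate_homeolog_pair
from hbcluster.synteny import (
    FlankingGeneSet,
    canonical_name,
    classify_cluster,
    dotplot,
    read_flank_tsv,
    shared_gene_matrix,
    windowed_identity,
)


def flank(species, cluster_id, *names):
    return FlankingGeneSet(species, cluster_id, [(n, "unknown") for n in names])


SALMON_CHR6 = flank(
    "salmon", "chr6",
    "C16orf35", "Rhomboid family member 1", "DOCK6", "ELAV-like protein 3", "MPG",
)
TETRAODON_C2 = flank(
    "tetraodon", "cluster2",
    "Rho-GTPase-activating protein", "Rhomboid family member 1",
)


class TestClusterTyping:
    def test_salmon_flank_is_cluster1_five_to_zero(self):
        r = classify_cluster(SALMON_CHR6)
        assert r.label == "cluster1"
        assert len(r.cluster1_hits) == 5
        assert r.cluster2_hits == []

    def test_tetraodon_second_cluster_is_ambiguous_one_to_one(self):
        r = classify_cluster(TETRAODON_C2)
        assert r.label == "ambiguous"
        assert r.cluster1_hits == ["Rhomboid family member 1"]
        assert r.cluster2_hits == ["Rho-GTPase-activating protein"]

    def test_empty_flank_is_ambiguous(self):
        r = classify_cluster(flank("x", "c"))
        assert r.label == "ambiguous"
        assert r.cluster1_hits == r.cluster2_hits == []

    def test_invariant_to_order_and_duplicates(self):
        shuffled = flank(
            "salmon", "chr6",
            "MPG", "mpg", "DOCK6", "C16orf35", "ELAV-like protein 3",
            "Rhomboid family member 1", "DOCK6",
        )
        assert classify_cluster(shuffled).label == classify_cluster(SALMON_CHR6).label
        assert classify_cluster(shuffled).cluster1_hits == classify_cluster(SALMON_CHR6).cluster1_hits

    def test_synonyms_canonicalize(self):
        assert canonical_name("MPG") == canonical_name("DNA-3-methyladenine glycosylase")
        assert canonical_name("Aqp8") == canonical_name("Aquaporin-8")


class TestSharedGeneMatrix:
    def test_identical_sets_give_all_true(self):
        m = shared_gene_matrix([SALMON_CHR6, flank("other", "c", *[n for n, _ in SALMON_CHR6.genes])])
        assert m.values.all()

    def test_disjoint_sets_give_block_diagonal(self):
        a = flank("a", "1", "gene one", "gene two")
        b = flank("b", "1", "gene three", "gene four")
        m = shared_gene_matrix([a, b])
        assert m["a|1"].tolist() == [True, True, False, False]
        assert m["b|1"].tolist() == [False, False, True, True]

    def test_pairwise_shared_counts_match_hand_tabulation(self):
        """Three constructed neighbourhoods with known overlaps (union of six names)."""
        a = flank("sp1", "c1", "C16orf35", "MPG", "DOCK6", "private one")
        b = flank("sp2", "c1", "C16orf35", "DOCK6", "Aquaporin-8")
        c = flank("sp3", "c2", "Aquaporin-8", "Rho-GTPase-activating protein", "MPG")
        m = shared_gene_matrix([a, b, c])
        shared = lambda x, y: int((m[x] & m[y]).sum())
        assert shared("sp1|c1", "sp2|c1") == 2  # C16orf35, DOCK6
        assert shared("sp1|c1", "sp3|c2") == 1  # MPG
        assert shared("sp2|c1", "sp3|c2") == 1  # Aquaporin-8
        assert m.shape == (6, 3)

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            shared_gene_matrix([SALMON_CHR6])

    def test_flank_tsv_reader(self, tmp_path):
        p = tmp_path / "flanks.tsv"
        p.write_text(
            "species\tcluster_id\tgene_name\torientation\n"
            "salmon\tchr6\tMPG\ttoward\n"
            "salmon\tchr6\tDOCK6\taway\n"
        )
        flanks = read_flank_tsv(p)
        assert len(flanks) == 1
        assert flanks[0].canonical_genes == [
            canonical_name("MPG"), canonical_name("DOCK6")
        ]


class TestDotplot:
    def test_self_comparison_has_full_main_diagonal(self):
        rng = np.random.default_rng(1)
        s = GenomicSequence("s", "".join(rng.choice(list("ACGT"), size=300)))
        dp = dotplot(s, s, word=12)
        hits = set(dp.forward)
        assert all((i, i) in hits for i in range(len(s) - 12 + 1))

    def test_reverse_complement_fills_reverse_channel(self):
        rng = np.random.default_rng(2)
        s = GenomicSequence("s", "".join(rng.choice(list("ACGT"), size=200)))
        rc = GenomicSequence("rc", revcomp(s.residues))
        dp = dotplot(s, rc, word=12)
        # every word of s matches the mirrored position of rc in reverse sense
        expect = {(i, len(s) - 12 - i) for i in range(len(s) - 12 + 1)}
        assert expect <= set(dp.reverse)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(3)
        a = GenomicSequence("a", "".join(rng.choice(list("ACGT"), size=150)))
        b = GenomicSequence("b", a.residues[30:120] + "ACGT" * 10)
        ab, ba = dotplot(a, b, word=10), dotplot(b, a, word=10)
        t = ab.transpose()
        assert t.forward == ba.forward
        assert t.reverse == ba.reverse

    def test_word_floor_enforced(self):
        s = GenomicSequence("s", "ACGTACGTACGT")
        with pytest.raises(ValueError):
            dotplot(s, s, word=4)

    def test_degenerate_short_sequence_gives_empty_matrix(self):
        s = GenomicSequence("s", "ACGTACG")
        dp = dotplot(s, GenomicSequence("t", "ACGTACGTACGTACGT"), word=8)
        assert dp.forward == [] and dp.reverse == []


class TestWindowedIdentity:
    def test_self_identity_is_one_everywhere(self):
        rng = np.random.default_rng(4)
        s = GenomicSequence("s", "".join(rng.choice(list("ACGT"), size=5000)))
        assert all(x == 1.0 for _, x in windowed_identity(s, s, window=500))

    def test_four_percent_divergence_reads_back_as_96(self, templates):
        (a, _), (b, _) = generate_homeolog_pair(chr6_config(5), 0.04, templates)
        idents = [x for _, x in windowed_identity(a, b, window=1000)]
        assert abs(float(np.median(idents)) - 0.96) <= 0.01
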