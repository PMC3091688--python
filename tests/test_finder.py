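import numpy as np
import pytest

from hbcluster.classifier import classify
from hbcluster.finder import (
    ExonHit,
    FinderConfig,
    chain_hits,
    find_exon_hits,
    find_genes,
)
from hbcluster.io_formats import GenomicSequence, revcomp
from hbcluster.pipeline import annotate_sequence
from hbcluster.reference import translate
from hbcluster.simulate import SimulationConfig, generate_cluster

from .oracles import enumerate_chains, sw_affine_score


def _spacer(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindExonHits:
    def test_planted_exact_exon_found_once(self, templates):
        rng = np.random.default_rng(0)
        cds = templates.exon("beta", 2).cds
        seq = GenomicSequence("s", _spacer(rng, 900) + cds + _spacer(rng, 900))
        hits = [h for h in find_exon_hits(seq, templates) if h.variant == "beta"]
        assert len(hits) == 1
        h = hits[0]
        assert (h.exon_index, h.strand, h.percent_identity) == (2, "+", 1.0)
        assert (h.start, h.end) == (900, 900 + len(cds))

    def test_strand_symmetry_of_hit(self, templates):
        rng = np.random.default_rng(0)
        cds = templates.exon("beta", 2).cds
        fwd = GenomicSequence("s", _spacer(rng, 900) + cds + _spacer(rng, 900))
        rev = GenomicSequence("s", revcomp(fwd.residues))
        h_f = [h for h in find_exon_hits(fwd, templates) if h.variant == "beta"][0]
        h_r = [h for h in find_exon_hits(rev, templates) if h.variant == "beta"][0]
        assert h_r.strand == "-"
        assert h_r.score == h_f.score
        assert (h_r.start, h_r.end) == (len(fwd) - h_f.end, len(fwd) - h_f.start)

    def test_diverged_template_recovered_and_score_matches_oracle(self, templates):
        rng = np.random.default_rng(3)
        tpl = templates.exon("beta", 2)
        pep = list(tpl.peptide)
        aa = list("ARNDCQEGHILKMFPSTWYV")
        for i in rng.choice(len(pep), size=round(0.1 * len(pep)), replace=False):
            pep[i] = aa[int(rng.integers(20))]
        mutated = "".join(pep)
        cds = "".join(
            {"A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
             "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
             "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
             "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT"}[a]
            for a in mutated
        )
        seq = GenomicSequence("s", _spacer(rng, 600) + cds + _spacer(rng, 600))
        hits = [
            h
            for h in find_exon_hits(seq, templates, min_identity=0.85)
            if h.variant == "beta" and h.exon_index == 2
        ]
        assert len(hits) == 1
        assert hits[0].percent_identity >= 0.85
        frame_prot = translate(seq.residues, phase=hits[0].ts_start % 3)
        assert hits[0].score == sw_affine_score(tpl.peptide, frame_prot)

    def test_empty_result_on_plain_spacer(self, templates):
        seq = GenomicSequence("s", _spacer(np.random.default_rng(5), 4000))
        assert find_exon_hits(seq, templates) == []


def _hit(exon_index, ts_start, length=120, strand="+", variant="beta", score=100.0):
    return ExonHit(
        seq_id="s", strand=strand, variant=variant, subunit="beta",
        exon_index=exon_index, start=ts_start, end=ts_start + length,
        score=score, percent_identity=0.95,
        ts_start=ts_start, ts_end=ts_start + length,
        q_start=0, q_end=length // 3,
    )


class TestChaining:
    def test_three_ordered_hits_form_one_complete_model(self):
        hits = [_hit(1, 0), _hit(2, 320), _hit(3, 640)]
        models = chain_hits(hits)
        assert len(models) == 1
        assert models[0].exon_indices == [1, 2, 3]
        assert models[0].defects == []

    def test_missing_middle_exon_becomes_partial_model(self):
        hits = [_hit(1, 0), _hit(3, 500)]
        models = chain_hits(hits)
        assert len(models) == 1
        assert models[0].exon_indices == [1, 3]
        assert models[0].missing_exons == [2]
        assert models[0].defects == ["missing_exon"]

    def test_interleaved_opposite_strand_chains_stay_separate(self):
        plus = [_hit(1, 0), _hit(2, 320), _hit(3, 640)]
        minus = [_hit(1, 150, strand="-"), _hit(2, 470, strand="-"), _hit(3, 790, strand="-")]
        models = chain_hits(plus + minus)
        assert len(models) == 2
        assert {m.strand for m in models} == {"+", "-"}
        assert all(m.exon_indices == [1, 2, 3] for m in models)

    def test_intron_bounds_respected(self):
        config = FinderConfig(intron_min=40, intron_max=3000)
        too_close = [_hit(1, 0), _hit(2, 130)]  # 10 bp gap
        models = chain_hits(too_close, config)
        assert len(models) == 2  # cannot be chained
        too_far = [_hit(1, 0), _hit(2, 5000)]
        assert len(chain_hits(too_far, config)) == 2

    def test_greedy_chain_matches_brute_force_on_toy_instance(self):
        rng = np.random.default_rng(11)
        hits = [
            _hit(int(i), int(p), score=float(s))
            for i, p, s in zip(
                rng.integers(1, 4, size=6),
                rng.choice(np.arange(0, 4000, 200), size=6, replace=False),
                rng.uniform(50, 150, size=6),
            )
        ]
        config = FinderConfig()
        best = max(
            enumerate_chains(hits, config.intron_min, config.intron_max),
            key=lambda c: sum(h.score for h in c),
        )
        got = max(chain_hits(hits, config), key=lambda m: m.score)
        assert got.score == pytest.approx(sum(h.score for h in best))


def _single_gene_cluster(seed, subunit, defect, **kw):
    cfg = SimulationConfig(
        seed=seed,
        n_alpha_functional=0,
        n_beta_bohr=0,
        n_beta_nonbohr=0,
        pseudogene_plan=((subunit, defect),) if defect else (),
        **kw,
    )
    return cfg


class TestRefinement:
    def test_intact_gene_refines_clean(self, templates):
        cfg = SimulationConfig(seed=21, n_alpha_functional=0, n_beta_bohr=1,
                               n_beta_nonbohr=0, pseudogene_plan=())
        seq, truth = generate_cluster(cfg, templates)
        models = find_genes(seq, templates)
        assert len(models) == 1
        m = models[0]
        assert m.defects == []
        assert m.has_start and m.has_stop
        assert all(ok for pair in m.splice_ok for ok in pair)
        assert m.exons == [iv for iv in truth[0].exons]
        assert m.protein_length == 148

    @pytest.mark.parametrize(
        "subunit,defect",
        [
            ("beta", "missing_exon"),
            ("beta", "bad_splice_donor"),
            ("beta", "bad_splice_acceptor"),
            ("beta", "internal_stop"),
            ("beta", "frameshift"),
            ("beta", "no_start"),
            ("beta", "no_stop"),
            ("beta", "length_violation"),
            ("alpha", "frameshift"),
            ("alpha", "missing_exon"),
        ],
    )
    def test_every_planted_defect_is_detected(self, templates, subunit, defect):
        """Generator coverage and finder/classifier detection agree for
        the full defect vocabulary."""
        seq, truth = generate_cluster(
            _single_gene_cluster(31, subunit, defect), templates
        )
        models = find_genes(seq, templates)
        assert len(models) == 1
        gene = classify(models[0], templates.config)
        assert gene.status == "pseudogene"
        assert defect in models[0].defects

    def test_frameshift_garbles_translation(self, templates):
        seq, _ = generate_cluster(_single_gene_cluster(31, "beta", "frameshift"), templates)
        m = find_genes(seq, templates)[0]
        assert "frameshift" in m.defects
        assert "internal_stop" in m.defects  # out-of-frame tail hits a stop

    def test_broken_donor_leaves_other_junction_intact(self, templates):
        seq, _ = generate_cluster(
            _single_gene_cluster(31, "beta", "bad_splice_donor"), templates
        )
        m = find_genes(seq, templates)[0]
        assert m.splice_ok[0][0] is False  # intron 1 donor broken
        assert m.splice_ok[0][1] is True
        assert m.splice_ok[1] == (True, True)


class TestFindGenes:
    def test_no_models_in_pure_spacer(self, templates):
        cfg = SimulationConfig(seed=2, n_alpha_functional=0, n_beta_bohr=0,
                               n_beta_nonbohr=0, pseudogene_plan=())
        seq, truth = generate_cluster(cfg, templates)
        assert truth == []
        assert find_genes(seq, templates) == []

    def test_strand_symmetry_of_full_finder(self, templates):
        cfg = SimulationConfig(seed=13, n_alpha_functional=1, n_beta_bohr=1,
                               n_beta_nonbohr=1, pseudogene_plan=(("beta", "internal_stop"),))
        seq, _ = generate_cluster(cfg, templates)
        rev = GenomicSequence(seq.id, revcomp(seq.residues))
        fwd_models = find_genes(seq, templates)
        rev_models = find_genes(rev, templates)
        assert len(fwd_models) == len(rev_models)
        L = len(seq)
        mirrored = sorted(
            (
                tuple(sorted((L - e, L - s) for s, e in m.exons)),
                {"+": "-", "-": "+"}[m.strand],
                tuple(m.defects),
                m.protein,
            )
            for m in rev_models
        )
        original = sorted(
            (tuple(sorted(m.exons)), m.strand, tuple(m.defects), m.protein)
            for m in fwd_models
        )
        assert mirrored == original
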