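import numpy as np
import pytest

from hbcluster.io_formats import read_truth_table, write_truth_table
from hbcluster.pipeline import annotate_sequence, compare_to_truth
from hbcluster.reference import translate
from hbcluster.simulate import (
    SimulationConfig,
    chr6_config,
    generate_cluster,
    generate_homeolog_pair,
    generate_lineage_cds,
    make_templates,
)


class TestTemplates:
    def test_alpha_translation_is_143(self):
        for seed in (1, 2010, 999):
            ref = make_templates(seed)
            assert len(ref.protein("alpha")) == 143

    def test_nonbohr_template_passes_all_hallmarks(self):
        for seed in (1, 2010):
            ref = make_templates(seed)
            p = ref.protein("beta_nonbohr")
            assert len(p) == 147
            assert p[-1] == "F"
            assert p[92] == "A"

    def test_bohr_template_has_cterminal_histidine(self, templates):
        assert templates.protein("beta")[-1] == "H"
        assert len(templates.protein("beta")) == 148

    def test_same_seed_reproduces_bundle(self):
        a, b = make_templates(7), make_templates(7)
        assert all(
            a.exon(v, i) == b.exon(v, i) for v in a.variants for i in (1, 2, 3)
        )

    def test_different_seeds_differ(self):
        assert make_templates(1).cds("beta") != make_templates(2).cds("beta")


class TestGenerateCluster:
    def test_canonical_composition_and_alternation(self, chr6_cluster):
        seq, truth = chr6_cluster
        assert len(truth) == 17
        subunits = [r.subunit for r in truth]
        assert all(a != b for a, b in zip(subunits, subunits[1:]))
        assert sum(r.status == "functional" and r.subunit == "alpha" for r in truth) == 6
        assert sum(r.bohr_status == "non_bohr" for r in truth) == 2
        assert sum(r.status == "pseudogene" for r in truth) == 5
        assert all(
            r.strand == ("-" if r.subunit == "alpha" else "+") for r in truth
        )

    def test_determinism_byte_identical(self, templates):
        a = generate_cluster(chr6_config(42), templates)
        b = generate_cluster(chr6_config(42), templates)
        assert a[0].residues == b[0].residues
        assert a[1] == b[1]

    def test_zero_genes_gives_pure_spacer(self, templates):
        cfg = SimulationConfig(seed=1, n_alpha_functional=0, n_beta_bohr=0,
                               n_beta_nonbohr=0, pseudogene_plan=())
        seq, truth = generate_cluster(cfg, templates)
        assert truth == []
        assert len(seq) > 0

    def test_unsupported_defect_rejected(self):
        with pytest.raises(ValueError, match="unsupported defect"):
            SimulationConfig(seed=1, pseudogene_plan=(("beta", "telomere_loss"),))

    def test_truth_table_round_trip(self, tmp_path, chr6_cluster):
        _, truth = chr6_cluster
        p = tmp_path / "truth.tsv"
        write_truth_table(truth, p)
        assert read_truth_table(p) == truth

    def test_zero_divergence_pipeline_reproduces_truth_exactly(self, templates):
        """With no background divergence and no defects the annotation
        must equal the truth in every field, including coordinates."""
        cfg = SimulationConfig(seed=8, template_divergence=0.0, pseudogene_plan=())
        seq, truth = generate_cluster(cfg, templates)
        res = annotate_sequence(seq, templates, chromosome_label="Chr6")
        assert compare_to_truth(res.genes, truth).perfect
        by_name = {r.name: r for r in truth}
        for g in res.genes:
            rec = by_name[g.name]
            assert g.model.exons == [iv for iv in rec.exons if iv is not None]
            assert g.strand == rec.strand

    def test_custom_strand_model(self, templates):
        cfg = SimulationConfig(
            seed=3, n_alpha_functional=1, n_beta_bohr=2, n_beta_nonbohr=0,
            pseudogene_plan=(), strand_model=("+", "+", "+"),
        )
        _, truth = generate_cluster(cfg, templates)
        assert [r.strand for r in truth] == ["+", "+", "+"]


class TestHomeologPair:
    def test_zero_divergence_gives_identical_sequences(self, templates):
        (a, _), (b, _) = generate_homeolog_pair(chr6_config(4), 0.0, templates)
        assert a.residues == b.residues

    def test_truth_tables_have_equal_gene_counts(self, templates):
        (a, ta), (b, tb) = generate_homeolog_pair(chr6_config(4), 0.04, templates)
        assert len(ta) == len(tb) == 17
        assert [r.status for r in ta] == [r.status for r in tb]

    def test_divergence_rate_is_respected(self, templates):
        (a, _), (b, _) = generate_homeolog_pair(chr6_config(4), 0.04, templates)
        frac = np.mean([x != y for x, y in zip(a.residues, b.residues)])
        # slightly below the nominal rate: rule-critical sites are shielded
        assert 0.033 < frac <= 0.041

    def test_copy_still_classifies_to_truth(self, templates):
        (a, ta), (b, tb) = generate_homeolog_pair(chr6_config(6), 0.04, templates)
        res = annotate_sequence(b, templates, chromosome_label="Chr6c")
        assert compare_to_truth(res.genes, tb).perfect


class TestLineageCds:
    def test_two_lineages_with_expected_sizes(self, templates):
        cds = generate_lineage_cds(9, templates)
        assert sum(1 for l, _ in cds if l.startswith("bohr")) == 8
        assert sum(1 for l, _ in cds if l.startswith("nonbohr")) == 6

    def test_sequences_are_coding_and_distinct(self, templates):
        cds = generate_lineage_cds(9, templates)
        assert len({s for _, s in cds}) == len(cds)
        for _, s in cds:
            assert "*" not in translate(s)
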