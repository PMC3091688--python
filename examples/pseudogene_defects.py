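"""Plant each pseudogenization defect and watch the pipeline call it.

One single-gene cluster per defect label: the beta gene carries exactly
that lesion, and the finder/classifier must report the gene as a
pseudogene with the matching defect.
"""

from hbcluster import classify, find_genes
from hbcluster.simulate import SimulationConfig, generate_cluster, make_templates

ref = make_templates(2010)
defects = [
    "missing_exon", "bad_splice_donor", "bad_splice_acceptor",
    "internal_stop", "frameshift", "no_start", "no_stop", "length_violation",
]
print(f"{'planted':<20}{'status':<13}{'failed criteria':<35}detected defects")
for k, defect in enumerate(defects):
    cfg = SimulationConfig(
        seed=300 + k, n_alpha_functional=0, n_beta_bohr=0, n_beta_nonbohr=0,
        pseudogene_plan=(("beta", defect),),
    )
    seq, _ = generate_cluster(cfg, ref)
    (model,) = find_genes(seq, ref)
    gene = classify(model, ref.config)
    print(f"{defect:<20}{gene.status:<13}"
          f"{','.join(sorted(gene.failed_criteria)):<35}{','.join(model.defects)}")
# Every planted lesion must turn the gene into a pseudogene; the
# detected defect list contains the planted label (an out-of-frame tail
# usually adds internal_stop on top of a frameshift).
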