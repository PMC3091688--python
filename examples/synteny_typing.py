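"""Type hemoglobin clusters from their flanking genes.

Teleost hemoglobin clusters fall into two ancestral types: Cluster 1
is flanked by C16orf35, Rhomboid family member 1, DOCK6, ELAV-like
protein 3 and MPG; Cluster 2 by Aquaporin-8 and Rho-GTPase-activating
protein.  Salmon carries two copies of Cluster 1 and no Cluster 2.
"""

from hbcluster.synteny import FlankingGeneSet, classify_cluster, shared_gene_matrix

flanks = [
    FlankingGeneSet("salmon", "chr6", [
        ("C16orf35", "toward"), ("Rhomboid family member 1", "away"),
        ("DOCK6", "toward"), ("ELAV-like protein 3", "away"), ("MPG", "toward"),
    ]),
    FlankingGeneSet("salmon", "chr3", [
        ("C16orf35", "toward"), ("DOCK6", "unknown"), ("MPG", "unknown"),
    ]),
    FlankingGeneSet("zebrafish", "second", [
        ("Aquaporin-8", "toward"), ("private gene", "unknown"),
    ]),
    FlankingGeneSet("tetraodon", "second", [
        ("Rho-GTPase-activating protein", "unknown"),
        ("Rhomboid family member 1", "unknown"),
    ]),
]

for f in flanks:
    r = classify_cluster(f)
    print(f"{f.species}/{f.cluster_id}: {r.label}"
          f"  (cluster1 hits: {len(r.cluster1_hits)}, cluster2 hits: {len(r.cluster2_hits)})")

print("\nshared-gene presence/absence matrix:")
print(shared_gene_matrix(flanks).replace({True: "x", False: "."}))
# Both salmon clusters type as Cluster 1 (the duplicated-copy claim);
# tetraodon's second cluster is ambiguous because it carries one
# signature gene from each set.
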