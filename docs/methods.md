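# Methods

This note documents the models, rules and numerical choices behind
`hbcluster`, what the synthetic data emulate (and what they do not),
and the known limitations.

## The annotation model

A vertebrate hemoglobin subunit gene is modelled as three exons and
two introns, with both introns falling between codons (phase 0, the
arrangement of vertebrate globin genes), canonical GT donor and AG
acceptor dinucleotides on the transcribed strand, an ATG at the start
of exon 1 and a stop codon at the end of exon 3. The α chain is 143
residues and the β chain 147 or 148, counted including the initiator
methionine and excluding the terminal stop.

### Exon search

Candidates are located by translated homology rather than ab initio
prediction: each exon's template peptide is searched against all six
reading frames of the input. Exact peptide 4-mers seed candidate
windows (merged per diagonal); each window is scored by Smith–Waterman
local alignment (BLOSUM62; affine gaps, a gap of length L costing
11 + L, Biopython's `PairwiseAligner` underneath). A window becomes an
`ExonHit` when its identity is ≥ `min_identity` (default 0.5) **and**
its score is ≥ `score_fraction` (default 0.3) of the template's
self-score. The score floor is what keeps random spacer sequence out:
on ~80 kb of simulated intergenic background no window ever reaches
0.3 × self-score, while true paralogs at ≤ 5% nucleotide divergence
score ≥ 0.9 × self. Peptide-level search keeps the scan insensitive to
synonymous divergence; nucleotide-level work happens only at
refinement.

### Chaining

Hits on one (strand, template-variant) pair are chained when exon
indices strictly increase in transcription order and the genomic gap
between consecutive exons lies within the intron bounds, default
**[40, 3000] bp**. The upper bound is deliberately tight: globin
introns are compact (~100–500 bp), and with realistic 2–5 kb
intergenic spacing a bound much above ~5 kb would allow a chain to
jump from one gene's exon 2 to the next same-strand gene's exon 3
whenever the neighbour's copy happens to score higher. Chains are
extracted greedily by descending chain score (ties: smaller total
intron length, then leftmost on the transcribed strand); each hit
joins at most one model. Complete 1-2-3 chains become gene
candidates; partial chains are kept as pseudogene candidates with
`missing_exon`. Because both β template variants (Bohr and non-Bohr)
match every β locus, overlapping same-strand models are resolved
afterwards by keeping the highest-scoring model per locus.

### Boundary refinement

Each exon of a chained model is re-anchored at the nucleotide level by
infix (semi-global) alignment of the template CDS against a padded
window (edlib). Alignment endpoints can drift a base or two when the
terminal template positions are diverged, so each boundary is then
*polished* to the position maximizing the exact match of the
boundary-proximal 12 template nucleotides (search radius ±3). Splice
checks are strict: the donor GT and acceptor AG must sit exactly at
the polished boundaries, otherwise `bad_splice_donor` /
`bad_splice_acceptor` is recorded and the homology boundary is kept.

Two plausible alternatives were rejected because they corrupt defect
calls on planted lesions. Maximizing spliced-translation identity
prefers frame-*restoring* spurious splice sites on frameshifted
pseudogenes, hiding the frameshift behind a fabricated junction.
Snapping to the nearest GT/AG in a ±12 nt window re-attaches mutated
donors to random intron GTs (~80% of planted broken donors were
mislabeled as frameshifts under that rule). Anchoring on homology
first and demanding the canonical dinucleotide exactly there
implements the criterion that junctions must align with those of known
functional genes, and detects planted splice lesions essentially
always.

The start codon is required at the polished exon-1 start (an ATG one
or two codons away is accepted only if its downstream translation
continues in frame with ≥ 6/8 matching residues); the stop is sought
in frame within ±4 codons of the template end of exon 3. Defects are
then recomputed: `no_start`, `no_stop`, `internal_stop` (stops are
retained in translations, never truncated), `frameshift` (any exon
whose observed length differs from the template by a non-multiple of
3), and `length_violation` (protein length outside the subunit rule).

### Classification

The three functionality criteria map directly onto the model:
`exon_count` (exactly 3 exons / 2 introns), `splice_and_termini`
(all splice junctions canonical, start/stop present, no internal stop
or frameshift, each exon peptide length within ±2 residues of its
template), and `protein_length` (143 for α; 147 or 148 for β). Any
failure makes the gene a putative pseudogene; the failed criteria and
defect labels are preserved. Functional β chains are screened for the
three non-Bohr hallmarks; the hallmarks are conjunctive, and position
93 is counted 1-based including the initiator methionine (the same
convention the length rule states explicitly; the config makes the
convention switchable via `nonbohr_position_includes_met` since only
the length rule is explicit about it).

### Layout and naming

Genes are ordered by start coordinate; the expectation model is α on
the negative and β on the positive strand, strict α/β alternation
(pseudogenes included by default), and the tail-to-tail motif counted
as adjacent pairs whose 3' ends face each other (upstream gene on +,
downstream on −). Names follow `Ssa<ChrLabel><α|β><k>` with
independent 5'→3' counters for functional genes and pseudogenes (ψ).
Strand expectations are anchored to the deposited orientation of the
assembly, so reverse-complementing an input flips them at every gene
while alternation violations and the tail-to-tail count are invariant;
this is intended behaviour, not a bug.

## Synteny and homeology

Cluster typing is presence/absence of the two signature flanking-gene
sets (Cluster 1: UPF0171 protein C16orf35, Rhomboid family member 1,
DOCK6, ELAV-like protein 3, MPG; Cluster 2: Aquaporin-8,
Rho-GTPase-activating protein), after name canonicalization
(case-fold, punctuation stripped) through a small synonym table; the
label goes to the set with strictly more hits, ties are `ambiguous`.
Raw hit counts, not weights — the underlying argument is qualitative
presence.

The dot plot records exact word matches (default word 15, step 1) in
separate forward and reverse-complement channels. Windowed identity
chains unique-in-both word anchors by longest increasing subsequence,
aligns the inter-anchor segments globally (edlib), and averages
per-position match flags over non-overlapping 1 kb windows of the
first sequence. Defaults (word 15, window 1000) keep the readout
stable on 100 kb inputs at the few-percent divergences of interest.

## Phylogenetics

Pairwise CDS distances are normalized edit distances (Levenshtein /
max length, via edlib). This choice is deliberate: "matches over
aligned columns" under a maximize-matches global alignment is not
well-defined (co-optimal paths differ in column counts), while
normalized edit distance is exact, symmetric and deterministic, and
coincides with the fraction of differing sites for the gap-free
high-identity comparisons this module is used for. Trees are built
with canonical neighbor joining (Q-criterion; deterministic
tie-breaking toward the lexicographically smallest label pair;
negative branch lengths clamped to zero with a warning). Monophyly on
the unrooted tree is exact: a leaf subset is a clade iff some edge
bipartitions the leaves into exactly that subset and its complement.
NJ replaces Bayesian inference because every claim checked here is
topological (clade membership), not a posterior probability; no
rooting claims are made anywhere.

## The synthetic generator

`simulate.generate_cluster` emulates the structure the analysis
assumes: alternating α/β genes on canonical strands, random GT…AG
introns (default 80–400 bp), random intergenic spacer (default 2–5 kb,
GC 0.43), functional genes as template copies with per-site
substitution at `template_divergence` (default 0.05), and pseudogenes
carrying exactly one planted lesion each. The default composition is
the chromosome-6-like cluster: 6 functional α, 4 Bohr β, 2 non-Bohr β,
2 α pseudogenes, 3 β pseudogenes. Rule-critical sites — start and stop
codons, splice dinucleotides, non-Bohr hallmark codons — are shielded
from background substitution, and any substitution that would create
an in-frame stop is rejected, so planted statuses are never silently
flipped; a soundness self-check re-derives every planted gene from the
emitted sequence at generation time. One global random stream per run
(NumPy `default_rng(seed)`) makes outputs byte-identical per config.

Planted lesions: missing exon = exon 2 removed (one intron-like gap
remains, still GT…AG); frameshift = single 1 nt deletion at a uniform
exon-2 position; premature stop = substitution creating TAA at a
uniform in-frame exon-2 codon; broken donor = intron-1 GT→AT; broken
acceptor = intron-2 AG→AA; lost start = ATG→GTG; lost stop = TAA→CAA;
length violation = one extra in-frame codon in exon 2.

`generate_homeolog_pair` emits a cluster and an independently mutated
copy at a stated divergence (default check: 4%), with the same
shielding plus whole-exon protection of pseudogenes so both truth
tables stay exact. Shielding makes the realized divergence run
slightly below nominal (~4% of sites are protected), which is why the
measured median windowed identity sits at ~96.2% rather than exactly
96.0% for 4% nominal divergence.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: repeat families and
transposable elements (real salmon BACs are repeat-rich; the score
floor substitutes for masking but was only validated against random
spacer), sequencing/assembly error and contig gaps, UTRs and promoter
context (genes are modelled as pure CDS exons plus stop), indel-driven
background divergence between paralogs (background divergence is
substitution-only; indels occur only as planted defects), and deep
pseudogene decay (lesions are single and recent; heavily eroded
"ghost" genes below the exon score floor are intentionally not
reported).

## Templates and the packaged reference bundle

Templates are plain per-exon peptide/CDS exemplars scored by
alignment, not trained probabilistic profiles: with a single exemplar
per exon a profile degenerates to alignment anyway. The packaged
bundle under `data/synthetic_salmon_reference/` is **synthetic** —
generated by `simulate.make_templates` (fixed seed 2010): α of 143
residues (exon lengths 31/68/44), Bohr β of 148 (30/74/44) with the
C-terminal histidine, and a non-Bohr β of 147 (30/74/43) derived from
the Bohr chain at ~8% peptide divergence with the hallmark residues
set. It is a structural stand-in for a curation of published salmon
globin clones, suitable for the synthetic study conditions and for
exercising the pipeline; annotating real salmon sequence is expected
to work best with templates curated from real cDNAs, supplied as a
bundle directory (`exon_peptides.fasta`, `exon_cds.fasta`,
`config.yaml`).

## Problem sizes and determinism

The shipped checks use 20 simulated clusters (~80 kb, 17 genes each)
for annotation accuracy, one ~75 kb homeolog pair, 14 CDS for the
clade property, 50 random additive matrices (5–12 taxa) for NJ
recovery, and 200 random peptide pairs (length ≤ 40) for alignment
oracle equivalence — sizes chosen so the whole suite re-derives every
claim in well under a minute on one CPU. All randomness is seeded;
reruns are bit-reproducible.

## Known limitations

- Multi-contig inputs are annotated per contig; no contig ordering is
  inferred (an explicit contig-order file is the supported route), and
  no unique gene order is asserted across contigs.
- The finder targets the α/β cluster families; the divergent α-D
  globin lineage is out of scope, as are EST support lookups (the
  corresponding report columns stay empty).
- Pseudogene reporting stops at the exon score floor: remnants too
  eroded to produce a qualifying exon hit are not reported as
  footprints.
- Boundary polishing assumes exon lengths close to the templates
  (true for globins); exotic splice variants shifting a junction by
  whole codons would be reported as defects rather than annotated as
  alternatives.
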