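# Methods

This note documents the models and algorithmic choices behind `metaribo`,
what the synthetic-community generator does and does not emulate, and the
numerical conventions that matter for reproducing its outputs.

## Lineage detection and the ribosomal-protein block

A lineage is anchored by a full-length ribosomal protein S3: protein length
≥ 200 aa, on a scaffold strictly longer than 5 kb, with uniqueness defined
at exact amino-acid identity (two scaffolds carrying identical RpS3 proteins
collapse to one lineage; two RpS3 genes on one scaffold keep the longest,
with a warning). The anchor scaffold is then scored for how many of the 16
ribosomal-protein families it carries. Family membership of a gene is its
best similarity hit (≥ 60 bits) among the 16 family references. The
retention rule for downstream analysis is **at least 8 of 16 families,
inclusive**. "More than half of 16" and "at least eight" differ at exactly
8/16; we adopt the inclusive reading and apply it both to lineage retention
and to taxon rows entering the concatenated alignment. Synteny breaks
(canonically adjacent family pairs that are non-adjacent or
strand-discordant on the scaffold) are reported as a diagnostic but never
used for filtering — the block search space is the whole anchor scaffold,
with an optional window deliberately left off by default.

## Abundance model

For lineage *i* in sample *s*:

    fraction_i(s) = coverage_i(s) × G_i / D_s

where `coverage_i(s)` is the anchor scaffold's mean read coverage, `G_i` the
predicted genome size, and `D_s` the sample's dataset size in bp. Predicted
genome sizes are configuration: 3 Mbp by default and 1.5 Mbp for phyla on
the small-genome list (seeded with the candidate phyla OD-1 and OP-11).
Fractions above 1 are clamped with a warning. The detection floor is the
same formula evaluated at the minimum mappable coverage (default 0.2×):
with a 3 Mbp genome and a 3 Gbp dataset this is 2×10⁻⁴, i.e. 0.02%.

Cross-sample displays normalize coverages by `max_t(reads_t) / reads_s`
(the deepest-sequenced sample is the reference; any reference choice gives
identical ratios). Recovery of planted abundances in tests uses raw
coverage with each sample's own dataset size, the exact inverse of the
generator's coverage model.

Rounding conventions: per-phylum percentages use half-away-from-zero to the
nearest integer; cross-depth ratios use largest-remainder integerization so
the reported triple sums to exactly 100, ties resolved toward the earlier
sample.

## Annotation tiers and taxonomy votes

Tiers are exclusive and exhaustive, first match wins: reciprocal best match
(both directions, forward best ≥ 300 bits and the reciprocal best of that
subject pointing back at the gene), one-way match (≥ 60 bits), motif-only
evidence, hypothetical. All threshold comparisons are inclusive. A scaffold
is assigned to the focal taxon when at least 40% (inclusive) of its genes
have a best hit to that taxon. Hypothetical genes count in the vote
denominator by default — the rule is read as "40% of genes", not "40% of
annotated genes" — and a flag flips this for users who prefer the laxer
reading.

## Alignment and phylogeny surrogates

Production workflows use MUSCLE-class aligners and maximum-likelihood
phylogenetics; this package deliberately replaces them with compact,
dependency-light surrogates adequate for tens of taxa:

* **Progressive alignment**: pairwise 3-mer distances → UPGMA guide tree →
  profile–profile Needleman–Wunsch with affine gaps (Gotoh), BLOSUM62
  scoring (loaded from Biopython), gap open 11, gap extend 1 (the first
  gapped column costs the open penalty, each further column the extension).
  Pairwise scores are verified in tests against an independent
  Needleman–Wunsch implementation.
* **Masking**: terminal columns that are gaps in any designated reference
  row are trimmed; interior columns with gap fraction > 0.5 are removed; a
  column map preserves traceability. This is an automated stand-in for
  manual curation of end gaps and ambiguous regions.
* **Concatenation**: partitions follow the canonical 16-family order;
  missing partitions are filled with `?` (distinct from the gap `-`);
  taxa present in fewer than 8 partitions are dropped.
* **Trees**: Saitou–Nei neighbor joining on protein p-distances with
  pairwise deletion (concatenated rows contain whole missing partitions, so
  complete deletion would discard most columns). Q-matrix ties break by the
  lexicographically smallest taxon pair; negative branch lengths clamp to
  zero with a warning. Bootstrap support resamples columns with replacement
  (default 100 replicates) and annotates each internal bipartition of the
  point tree with the percentage of replicates containing it. Taxonomic
  placement is nearest-reference by p-distance with a tie → unclassified
  rule; pairs sharing < 50 comparable columns are flagged, < 10 is an error.

## Tetranucleotide binning

Scaffolds ≥ 5 kb map to 136-dimensional vectors: sliding 4-mers on one
strand, each counted toward its canonical class (lexicographically smaller
of the 4-mer and its reverse complement; 120 complementary pairs + 16
palindromes), windows containing ambiguous bases skipped, normalized to sum
to 1. Canonicalization makes the vector exactly invariant under reverse
complementation.

The map is a classic online Kohonen SOM: default 50×50 toroidal grid, 20
epochs, learning rate decaying linearly 0.5 → 0.01 and Gaussian
neighborhood radius max(rows, cols)/4 → 1 over the run, weights initialized
uniformly in the per-dimension data range from the mandatory seed. Training
is deterministic given the seed. A warning is emitted when the grid has
fewer than 4 nodes per input, since emergent cluster structure needs map
head-room.

Bins are harvested from the U-matrix (per-node mean distance to its 8 grid
neighbours, toroidal). The raw U-matrix is speckled, so it is smoothed with
two passes of a 3×3 mean filter — the same treatment ESOM viewers apply
before display — and nodes below the 30th percentile form a valley mask.
Connected components of the mask (8-adjacency, toroidal) define bins;
scaffolds inherit their best-matching unit's component, and scaffolds whose
BMU falls outside the mask (or in a component backed by fewer than 5
scaffolds) are attached to the nearest kept component by grid distance.
This whole harvesting stage is an automated surrogate for the manual
polygon selection used with interactive ESOM tools; the percentile,
smoothing passes, and minimum component size are configuration, and no
claim of equivalence to manual curation is made.

Bin curation iterates to a fixed point, removing scaffolds whose GC z-score
against the current bin exceeds 2, whose per-sample coverage profile
correlates with the bin's median profile below 0.9 (Pearson), or whose
taxonomy vote contradicts the bin's taxon at ≥ 0.5. Curation is idempotent;
rejecting every scaffold is an error.

Completeness = distinct single-copy marker families present / 76 (families
present more than once are reported as a duplication/contamination signal);
the marker list is configuration, and a list of a different length warns
and becomes the denominator. The genome-count estimator averages each
marker family's occurrence count over all 76 families and rounds half away
from zero — on k pooled complete genomes it returns exactly k.

## The synthetic-community generator

The generator produces exactly the statistical structure the pipeline
consumes, with truth tables for scoring:

* **Composition**: each genome samples from an order-3 Markov chain whose
  64×4 transition table is `(1 − s)·T_global + s·T_private`, where
  `T_global` is a fixed package-wide table drawn once from a mildly
  concentrated Dirichlet (seeded constant) and `T_private` is a
  genome-specific Dirichlet draw from the genome's composition seed. The
  mixing weight `s` (`signature_strength`) is the planted tetranucleotide
  signal: at 0 all genomes share one composition; at 0.3 genome centroids
  separate well beyond within-genome fragment scatter. An order-3 chain
  gives genuine 4-mer structure, which is what the binner reads.
* **Planted genes**: the 16-family rp operon is inserted colinearly in
  canonical order on the + strand; marker genes at random non-overlapping
  positions. Planted proteins are synthetic family references (fixed-seed
  random sequences with realistic lengths; RpS3 is 218 aa, above the
  full-length filter) carrying Poisson(divergence × length) substitutions,
  back-translated with codon weights taken from the host genome's own
  trimer frequencies so planted genes do not disturb its signature.
* **Fragmentation**: scaffold lengths follow min_len + Exp(mean_len −
  min_len); scaffolds tile the genome exactly. Breakpoints falling inside a
  planted feature — including the whole operon span — are pushed to the
  feature's end, so planted truths (block fractions, marker counts) are
  exact by construction; in exchange, the generator never produces genes
  truncated by scaffold edges, a real-data artifact the fixtures do not
  model.
* **Coverage**: `coverage(g, s) = abundance[g, s] × dataset_bp[s] /
  predicted_genome_size[g]`, shared by all scaffolds of the genome, times
  mean-one multiplicative lognormal noise `exp(σZ − σ²/2)` with default
  σ = 0.1; σ = 0 is reserved for exact-inversion tests. Per-sample read
  totals assume 150 bp reads.
* **Hits**: every surviving gene gets a forward hit to a genome-specific
  synthetic database subject with bits ~ U(310, 600) and a matching
  reciprocal row; with false-positive rate `fp`, a gene instead gets a
  one-way hit with bits ~ U(61, 299), and subject taxa are mislabeled with
  probability `fp`.

Default fixture scales were chosen once as realistic for the study design
being emulated: three to five genomes per community, three samples (multi-
depth), genome abundances of 0.05–2% against multi-Gbp datasets, 5 kb
minimum scaffolds. The bin-recovery experiments use five 1.5 Mbp genomes
fragmented at ~7 kb mean so each genome yields ≥ 200 scaffolds above the
tetra length filter.

What the generator does **not** emulate: read-level error, strain
microdiversity, shared/horizontally transferred genes, composition that
varies along a genome (GC skew, prophages), truncated edge genes, chimeric
scaffolds, or database incompleteness. Passing tests therefore demonstrate
the pipeline's internal correctness and its behaviour under the stated
statistical model, not performance on real assemblies.

## Determinism and numerical conventions

All stochastic steps take explicit seeds (numpy `default_rng`); identical
config + seed reproduces byte-identical fixtures and outputs, which the
test suite verifies end to end. Coordinates are 1-based inclusive
(GFF3 dialect); protein length is (end − start + 1)/3 − 1, excluding the
stop codon. Best-hit ties break by higher percent identity, then input
order. The missing symbol `?` and the gap `-` are distinct throughout.

## Known limitations

* The SOM harvester can merge genomes whose signatures are close at low
  `signature_strength`; the adjusted Rand index of recovery is a stochastic
  quantity, reported as a multi-seed mean.
* Neighbor joining on p-distances underestimates deep divergences
  (no substitution-model correction); bootstrap values on short
  concatenations are optimistic.
* The progressive aligner is O(L²) per merge and intended for
  ribosomal-protein-scale families, not genome alignments.
* Genome-count estimation assumes the marker suite is truly single-copy;
  duplicated markers inflate the estimate and are only surfaced, not
  corrected.
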