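# Methods

This note documents the models and procedures implemented in `bmirnet`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Study system

B chromosomes are dispensable supernumerary elements carried by some
individuals (B+) and absent in others (B-). In the cichlid system this
package targets, a B chromosome is a mosaic of duplicated A-chromosome
segments, so B-derived loci show up as regions of the standard assembly with
roughly doubled genomic read coverage in B+ libraries ("B-blocks"), and the
presence of the B perturbs the expression of A-complement miRNAs. The
pipeline asks four questions: what is the miRNA catalog of the genome, do
any miRNA loci sit on the B, which miRNAs respond to B presence, and which
protein-coding targets and interaction neighborhoods those responders hit.

## miRNA catalog

* **Read preprocessing.** Reads are truncated at the first occurrence of the
  3' adapter (`TGGAA` by default) and kept only if the trimmed length lies
  in [17, 27] nt, the mature-miRNA size range. Trimming is idempotent.
* **Reference collapsing.** The reference mature list is made nonredundant
  by removing exact duplicates and full-length substrings of a longer
  retained sequence (longest representative, ties to the lexicographically
  smallest id). This mirrors clustering of a public fish miRNA set into a
  nonredundant reference.
* **Hairpin test.** Instead of a full probabilistic precursor model, a
  candidate window is partitioned into (5' arm, loop, 3' arm) with equal
  arm lengths in [20, 24] nt and loop in [8, 15] nt; the score is the
  fraction of positions in which the 5' arm pairs the reversed 3' arm by
  Watson-Crick rules, counting the G.U wobble as paired (configurable).
  A hairpin is called when the best partition reaches complementarity 0.6.
  Partitions cover the whole window; genome-scale use slides the test over
  candidate windows. Longer arms win score ties. On uniform-random 60-nt
  windows the false-call rate at 0.6 is a few percent; planted perfect
  inverted repeats always score 1.0.
* **Known/novel classification.** A precursor is *known* when a mature arm
  matches a reference mature with at most 2 full-length mismatches and an
  identical seed (nt 2-8 from the 5' end); otherwise *novel*. Novel
  precursors whose seed exactly equals a reference seed inherit that
  reference id as their seed family (ties: fewest full-sequence mismatches,
  then lexicographic id). The 2-mismatch bound is an explicit, testable
  criterion chosen because upstream tools leave their tolerance implicit.
* **Arm dominance.** The arm with the strictly larger summed read count is
  dominant; ties (including zero evidence) default to 5p with a flag.
* **Clustering.** Single-linkage chaining per contig: precursors sorted by
  start join one cluster while the inter-precursor gap (next start minus
  previous end) is at most 5000 bases, inclusive; overlaps join. Strand is
  ignored (published clusters mix strands). Clusters have at least 2
  members; everything else is a singleton.
* **Summary.** Counts plus percentages rounded half-even to 2 decimals,
  matching the printed precision of the source tables.

Coordinates are 0-based half-open internally; GFF3 is read and written
1-based inclusive.

## B-chromosome screening

* **Coverage ratio (strategy 1).** Depth tracks for the B- and B+ genomic
  libraries are averaged into 1-kb windows (overlap-weighted for per-base
  or irregular input intervals). Each library is scaled by its genome-wide
  median window depth, so a global sequencing-depth difference cancels, and
  the per-window ratio is (B+/median+) / (B-/median-). Windows with zero B-
  depth are flagged undefined and excluded. B-blocks are maximal runs of at
  least 3 windows with ratio >= 1.5, bridging single sub-threshold windows;
  the block ratio averages the elevated members. The expectation for a
  B-duplicated segment is ratio 2 (e.g. 60x vs 120x); the 1.5 calling
  threshold admits Poisson noise around 2x at moderate depth while
  excluding single-copy regions. Window size and both thresholds are
  configurable. Intersecting called blocks with precursor annotations
  reports any miRNA gene inside a duplicated region; an empty intersection
  is a valid, reportable outcome.
* **Unaligned-read rescue (strategy 2).** Reads that place nowhere on the
  reference assembly at <= 1 mismatch are aligned to the B+ assembly (both
  strands, plain substring search with mismatches — adequate for 17-27-nt
  reads and dependency-free). Placements within 100 bases group into
  candidate loci; a locus is B+-exclusive only when every supporting read
  comes from B+ samples. A locus supported by both genotypes is the
  assembly-gap signature, not a B locus.
* **Restricted-reference prediction (strategy 3)** is a pipeline
  configuration, not new code: the catalog-stage hairpin test run with the
  called B-blocks as the only reference intervals.
* **Gene dose ratio.** Per sample, dCq = Cq(target) - Cq(reference gene,
  UBCE by default); ddCq is the difference of group means (B+ minus B-) and
  the dose ratio is 2^-ddCq. Per-sample dCq removes per-sample offsets, so
  the estimate is invariant to sample-wide Cq shifts; swapping group labels
  inverts the ratio. Significance uses a two-sided Wilcoxon rank-sum test
  on the per-sample dCq values — group sizes are small and no normality is
  assumed. With sigma = 0.2 cycles of qPCR noise and equal copy number the
  test is non-significant in well over 90% of simulated experiments.

## Differential expression

* **Filtering.** Rows are kept when CPM >= 1 in at least `min_samples`
  samples (inclusive boundary).
* **TMM normalization.** The reference library is the one whose 75th count
  percentile (scaled by library size) is closest to the mean across
  libraries. Gene-wise log2 ratios (M) and average abundances (A) against
  the reference, over genes positive in both, are doubly rank-trimmed (30%
  on M, 5% on A) and averaged with inverse asymptotic-variance weights;
  factors are rescaled to product 1. On a fixed seeded matrix the factors
  agree with the Bioconductor edgeR implementation to 1e-4.
* **Exact test.** Dispersion is fixed at phi = BCV^2 with BCV = 0.4 — a
  deliberate, literal choice rather than tagwise estimation. Effective
  library sizes (library size x TMM factor) are equalized by linearly
  scaling each sample's counts to the geometric-mean effective size (full
  quantile adjustment is not implemented; at the near-equal library sizes
  of the simulated designs the distortion is negligible). Conditional on a
  miRNA's total count t, the split between group totals follows a
  beta-binomial law with shapes n_a/phi and n_b/phi that does not depend on
  the unknown mean (binomial in the Poisson limit phi = 0); the two-sided p
  sums the probabilities of all splits as or less probable than the
  observed one, so a perfectly symmetric split gives p = 1. In a null
  simulation (fc = 1, BCV 0.4, 3 vs 3, 2500 miRNAs) the rejection rate at
  alpha = 0.05 sits inside the binomial 95% CI.
* **Fold change.** log2 FC uses normalized group means with a prior count
  of 0.125 per side to avoid log of zero; the reported linear fold change
  is signed (+FC up, -FC down, |FC| >= 1).
* **DE call.** p < 0.05 (raw) and linear |FC| > 1.5, both strict. The raw-p
  rule is faithful to the source protocol; a Benjamini-Hochberg option
  exists but is off by default. The nonredundant DE set is the union over
  contrasts keyed by mature id, with per-tissue Venn counts.

## Target prediction

* **3'UTR extraction.** The 3'UTR is the subsequence strictly downstream of
  the stop codon. Transcripts are assumed oriented, so when no ORF
  annotation is supplied the longest forward-frame ORF (ATG to stop, >= 100
  codons including the stop) is located first. Transcripts with no
  downstream sequence are skipped; malformed records are reported and
  processing continues.
* **Seed sites.** The scanner finds each occurrence of the 6-nt core
  (reverse complement of miRNA positions 2-7) and classifies it by two
  flanking features: the UTR base 5' of the core pairing miRNA position 8,
  and the UTR base 3' of the core being an A (opposite miRNA position 1).
  Both gives an 8mer, m8 only a 7mer-m8, A only a 7mer-1A; a bare core is
  not a site. Candidates within 7 nt are mutually exclusive — the stronger
  type wins (8mer > 7mer-m8 > 7mer-1A), then the 5'-most. U and T are
  interchangeable on input.
* **Scoring.** Each site contributes a configurable negative weight
  (defaults -0.31 / -0.16 / -0.10, implementation constants patterned on
  mean context contributions of the canonical site types); the interaction
  total is their sum and an interaction is significant when the total is
  strictly below -0.2. The full context model (local AU content, position
  in UTR, 3'-supplementary pairing, conservation) is intentionally not
  reimplemented: the score is used only as a binary filter, and the
  additive form reproduces that decision structure.
* **Per-tissue prediction** restricts to transcripts expressed in the
  requested tissue and orders output by (miRNA id, transcript id).
  Interactions are keyed by transcript; collapsing to gene symbols happens
  only at network entry.

## Network integration

* **B-related proteins** are the exact intersection of per-group target
  sets (three tissues by default, each the union over sexes; configurable
  to six tissue x sex groups), with Venn region counts. Symbols are
  upper-cased before matching to bridge case conventions.
* **Interaction filtering** keeps rows where both taxids equal 9606 and the
  detection method is one of seven PSI-MI codes (MI:0004 affinity
  chromatography, MI:0114 X-ray crystallography, MI:0047 far western,
  MI:0055 FRET, MI:0090 protein complementation, MI:0045 experimental
  detection, MI:0018 two hybrid). The MI token is extracted by exact regex
  from free-text fields. Pairs are canonicalized by sorted symbols;
  self-loops and duplicates are dropped, with per-rule removal counts. The
  filter is idempotent.
* **Subnetwork extraction** induces the subgraph on the seed symbols (both
  endpoints seeds) and drops isolated seeds. A first-neighbor expansion
  mode exists but induced-only is the default, the reading most consistent
  with the source network's node count being far below its seed count.
* **B-miR-net assembly** merges deduplicated directed miRNA->protein edges
  into the PPI subgraph. Regulatory edges to proteins absent from both the
  subgraph and the tissue-specific target lists are dropped and logged.
  Node provenance is labeled (B-gene > B-related > neighbor;
  tissue-specific target for miRNA-only proteins) and total edges equal
  PPI plus regulatory edges with no double counting.
* **Integrity partition** splits B-genes at > 80% coding integrity,
  strictly: a gene at exactly 80.00 falls in the truncated class (the
  bundled table's 80.25 is intact, 79.90 truncated). Both halves sort by
  descending integrity.
* **Enrichment** is a hypergeometric upper tail per term (k selected of K
  background carriers, n drawn from N) with Benjamini-Hochberg q-values
  over the tested terms; terms absent from the selection are untested. The
  default reporting cutoff is q < 0.05. Exclusive terms between two
  enriched sets are a plain set difference, with the shared set also
  reported. GO graph propagation is out of scope — the annotation is taken
  as given.

## Synthetic data

The generator plants every signal the pipeline is built to detect, under
one integer seed with an independent RNG stream per generator (so adding or
reordering calls leaves the others' output byte-identical).

Defaults are the study conditions: base depth 60x with 2x over B-blocks,
BCV 0.4, planted linear fold change 1.5, four replicates per group, 80%
dominant-arm read bias, adapter `TGGAA`. Background sequence is uniform
over {A, C, G, T}; accidental seed matches are re-randomized for a few
passes where feasible and any residue is recorded in the truth rather than
forbidden, avoiding rejection-sampling bias. Adapters are 3' suffixes only,
matching the implied library chemistry. Depth is Poisson per 1-kb window;
counts are negative-binomial with the planted DE set shared across
contrasts; interaction tables carry flagged duplicate, self-loop,
foreign-taxon and disallowed-MI rows; Cq tables encode known dose ratios
through shifted dCq with 0.1-cycle noise.

Not emulated: base-call errors, quality scores, isomiR heterogeneity,
alignment ambiguity from repetitive sequence, GC or length biases in
coverage, correlated library composition shifts, and real secondary
structure (arms pair perfectly by construction). Passing tests therefore
demonstrate correctness of the statistical machinery and the decision
rules under the assumed models, not robustness to those real-data
artifacts.

## Problem sizes and tolerances

Simulation-based checks run at sizes chosen to make their statistical
assertions sharp but cheap: 50 replicate genomes (3 contigs x 60 kb, five
10-kb blocks) for block-calling recall/precision >= 0.9 at 30x; one 1000x
replicate for the |ratio - 2| < 0.05 convergence check; 2500 null miRNAs
for test calibration inside the binomial 95% CI; 100 random miRNA/UTR
pairs, random graphs up to n = 50 and totals up to 30 for the brute-force
oracle equivalences (p-value agreement to 1e-10); 100 replicate qPCR
experiments for the equal-copy non-significance rate. Ties in floating
p-mass comparisons use a 1e-10 relative tolerance.

## Known limitations

The exact test equalizes library sizes by linear scaling rather than
quantile adjustment; with strongly unequal libraries the conditional law is
approximate. The rescue aligner is exact/1-mismatch substring search, not a
gapped aligner. Known/novel classification uses mature-sequence similarity
only. The hairpin test does not fold RNA and will accept any
high-complementarity inverted repeat, structured or not.
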