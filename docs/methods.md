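# Methods

`ecckit` analyses eccDNA (extrachromosomal circular DNA) call sets of the
kind a Circle-seq caller emits: one interval per detected circle with a
confidence score ("circle score") and a junction-spanning read count. The
package covers the downstream analysis only — characterization of the
call set, breakpoint-flank motif enrichment, differential abundance
between two conditions, annotation-term enrichment, and association of
eccDNA loci with genes, miRNA precursors and circRNA back-spliced
junctions. Read alignment and circle calling are out of scope; the
caller's output tables are the input.

All internal coordinates are 0-based half-open. GFF3 (1-based closed) is
converted at the I/O boundary. Circles are treated as strandless
throughout: records carry strand "." and no predicate consults strand.

## Input model and filtering

An eccDNA record is `(chrom, start, end, name, circle_score,
junction_reads)`. Records with circle score <= 0 are dropped on read —
the standard confidence filter for this caller output — with the drop
count logged, not raised. The junction read count serves as the locus
abundance; no other caller columns are modelled because downstream use
of the remaining columns is tool-specific.

## Locus catalog and presence/absence partition

Loci are matched across samples by their junction coordinates. The
default is exact matching (tolerance 0); a bp tolerance merges records
by single linkage within a chromosome when both start and end differ by
at most the tolerance, taking the smallest enclosing interval and
summing per-sample reads. Exact matching is the defensible default
because a caller assigns identical breakpoints to re-detections of the
same circle; the tolerance exists for cross-caller coordinate dialects
(which commonly differ by ±1).

A locus is "detected" in a condition when any replicate has a positive
count. The two-condition Venn partition (A-only / B-only / shared) is
asserted disjoint and exhaustive on every run.

## Characterization

* Per-chromosome counts, and densities as count / (length/1e6).
* Element classes: a locus overlapping any gene body by >= 1 bp is
  genic, otherwise intergenic; genic loci overlapping any exon by
  >= 1 bp are exonic, else intronic. The 1 bp rule is the simplest
  reproducible partial-overlap convention; the threshold is a parameter.
* Size histogram over half-open bins, default edges
  {0, 100, 1000, 10000, 20000} bp, with an explicit overflow bin.
* GC metaprofile: each locus body plus an upstream and downstream flank
  of one locus length are rescaled to a fixed number of bins and the GC
  fraction averaged across loci, reported against the genome-wide GC.
  Scaling the flank to the locus length makes the profile comparable
  across the three-decade size range; loci whose flank would cross a
  chromosome end are skipped and counted.

## Breakpoint motifs

For each locus the 10 bp on either side of both breakpoints are
extracted: a 20-mer centred on the start (5' breakpoint) and one centred
on the end (3' breakpoint). Position frequency matrices (rows normalized
over A/C/G/T; other characters excluded from that position's
denominator) are compared against a randomized-reposition null: in each
of `n_perm` permutations (default 100) every locus is re-placed at a
uniformly random position genome-wide — chromosome chosen with
probability proportional to its number of placeable positions, length
preserved — and the PFMs recomputed. The enrichment statistic is the
elementwise z-score against the permutation mean and sd, with the sd
floored at 1/(2·n_sequences) so cells the null never varies in cannot
produce infinities. A per-position AT-content excess
(obs(A)+obs(T) − null(A)−null(T)) summarizes AT-richness.

Calibration note: the z-scores are well calibrated when the loci truly
come from the position-independent law the null models; comparing |z| to
a Bonferroni-corrected normal quantile requires enough permutations
(≈200) that the estimated sd does not inflate the extreme tail.

## Differential abundance

Fold change is log2 of the mean-CPM ratio with a pseudocount of 1
(condition-specific loci otherwise have infinite fold change). Three
tests are available:

* `pooled-fisher` (default for eccDNA): per feature, a 2×2 Fisher exact
  test of condition-pooled feature counts against the rest of the
  pooled library. Powerful and assumption-light, but its p-values are
  discrete and it ignores biological replicate variability, so it is
  anticonservative under strong overdispersion.
* `logcpm-t`: two-sample pooled-variance t on log2(CPM+1) across
  replicates. With the tiny group sizes typical of these designs (n=3)
  this is the calibrated replicate-aware choice: it is exact under
  normality at equal group sizes, and its null p-values are
  indistinguishable from uniform on negative-binomial counts at
  dispersion 0.1.
* `welch-logcpm`: the unequal-variance (Satterthwaite) variant. Kept
  for completeness; at n=3 the Satterthwaite degrees of freedom are
  measurably anticonservative even on normal data, so `logcpm-t` is
  preferred.

Features are called up/down when raw p < alpha (default 0.05) and
|log2fc| > 1; Benjamini–Hochberg q-values are always reported and can be
made the gate (`strict_fdr`). The raw-p gate is the classical screening
rule for this kind of study; the q column makes the FDR cost visible.
BH is the standard step-up procedure, q_(i) = min_{j>=i} m·p_(j)/j
capped at 1, cross-checked in the tests against an independent
reference implementation.

Normalization is CPM for count tables (columns sum to 1e6) and
length-aware TPM when feature lengths are supplied (the convention for
miRNA tag counts).

## Association rules

* eccDNA per gene: a catalog locus counts toward every gene body it
  overlaps by >= 1 bp; Spearman correlation (ties mid-ranked, zero-count
  genes included) between these counts and mean normalized expression
  is reported per condition.
* Density coupling: per chromosome, eccDNAs/Mb and coding genes/Mb,
  their ratio, and the Spearman correlation across chromosomes.
  Chromosomes with zero genes keep their densities but have an
  undefined ratio (NaN).
* miRNA containment: a precursor associates with a locus that fully
  covers it (non-strict containment, strand ignored) — the condition
  under which the eccDNA could encode the miRNA.
* circRNA junction sharing: a back-spliced junction matches an eccDNA
  junction when both coordinates agree within a tolerance (default 0,
  exact); each circRNA is counted once however many loci it matches. A
  one-end mode (either coordinate matching) is a flag.
* circRNA locus sharing: full containment of the circRNA interval, same
  contract as miRNA containment.
* A circRNA on a locus is called "expressed" when its coverage value on
  that locus is strictly positive. Coverage arrives as a plain numeric
  per-pair table, keeping the rule testable without browser-track files.

Every predicate is re-checked in the test suite against brute-force
all-pairs or per-base scans on randomized instances.

## Term enrichment

Generic over-representation for any feature set: hypergeometric upper
tail P[X >= k] for k hits of a K-member term in an n-feature query from
an N-feature universe, BH-corrected across terms. The gate defaults to
raw p <= 0.05 with q reported (a q-gate is a flag). The universe
defaults to all annotated genes. No ontology content ships with the
package; the term map is a caller-supplied two-column TSV.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
so every stage is testable against known truth without any downloads:

* Genome: i.i.d. bases at a configurable GC content (default 0.38, an
  AT-rich insect-like genome), several chromosomes.
* Genes: non-overlapping, both strands, fixed exon count per gene
  (default 3, exons filling 40–80% of equal blocks). Genes are
  apportioned to chromosomes by length times a linear density gradient
  (`gene_density_span`, default 2.0 = highest/lowest genes-per-Mb
  ratio) so the density-coupling statistic has structure to find.
* eccDNA loci: lengths log-uniform on [72, 17000] bp, so the
  100–1000 bp class dominates; a configurable fraction placed
  overlapping genes, the rest placed in intergenic space by rejection.
  Note the two placement channels interact: gene-dense chromosomes
  attract genic loci but repel intergenic ones, so the sign of the
  eccDNA-vs-gene-density coupling depends on the genic fraction
  relative to the genome's gene coverage.
* Motif planting rewrites the genome with the motif (default ATATAT)
  immediately 5' of both breakpoints of a chosen locus fraction, making
  the enrichment effect size exactly controllable.
* Junction reads: negative binomial with var = mu + d·mu² (Poisson at
  d=0), baseline mean 50 reads, dispersion 0.1 by default. Differential
  loci split the planted log2 fold change (default 2) symmetrically
  between conditions; condition-specific loci have their counts zeroed
  in the other condition but stay in the truth table, so presence/
  absence logic is checkable. A record is emitted only when its count
  is positive; a detection guarantee bumps a locus to one read in its
  intended condition in the (rare at mean 50) event of an all-zero draw,
  so the catalog equals the truth locus list exactly.
* circRNAs: a configurable fraction copies eccDNA junction coordinates
  exactly (the flag count is exact after rounding); the rest are placed
  anywhere that does not coincide with an eccDNA junction.
* miRNA precursors (default 80 bp): a configurable fraction strictly
  inside eccDNA loci, the rest placed outside by rejection.
* Expression: per-gene means are lognormal around a Gaussian-copula
  latent coupled to the per-gene eccDNA count. Because the counts are
  heavily tied (many zero-eccDNA genes), the realized Spearman
  correlation is attenuated; the generator solves the latent coupling
  weight by bisection against the realized value so the emitted data
  hit the requested `expr_coupling_rho` (or the tie-limited maximum if
  the target is unreachable). Per-sample counts are negative binomial
  around those means.

Identical configurations (including seed) produce byte-identical files.
What the generator does not emulate: read-level artefacts (chimeras,
rolling-circle amplification bias), sequence-dependent circle formation
(hotspots arise only through the gene-density gradient), locus-length/
abundance coupling, and replicate-level batch structure. Passing tests
therefore demonstrate correctness of the downstream computations under
the stated model, not robustness to upstream artefacts in real
libraries.

## Pipeline, determinism and problem sizes

One YAML config drives simulate → characterize → motifs → differential
→ associate → enrich; any stage subset can be run, thresholds are all
overridable, and a manifest records the config snapshot, input SHA-256
checksums, seed and stage outputs. All randomness flows from the single
seed through `numpy.random.default_rng`; fixed-seed reruns are
byte-identical except for the manifest timestamp.

The test suite and the acceptance script run on simulated studies of
300–1500 loci on multi-megabase genomes with 100–200 permutations and
20 replicate simulations per calibration check — sizes at which every
statistic is stable while the whole suite completes in well under a
minute of compute per module.

## Known limitations

* The Fisher default inherits the pooled test's anticonservatism under
  strong overdispersion; use `logcpm-t` (or `strict_fdr`) when replicate
  variability matters more than power.
* Single-linkage catalog merging with a large tolerance can chain
  distinct loci; tolerance 0 avoids this entirely.
* The per-chromosome density correlation across few chromosomes has
  very low resolution (Spearman over a handful of points).
* GO/KEGG term content, miRNA target prediction and network
  visualization are intentionally out of scope.
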