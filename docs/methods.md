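# Methods

## Model and assumptions

The package treats Sleeping Beauty (SB) insertion calling as solved
upstream: inputs are per-specimen tables of (chromosome, TA position,
transposon strand, supporting read depth). All statistics condition on
the TA-dinucleotide landscape of the reference genome, because SB
integrates essentially only at TA. Every position whose dinucleotide
reads TA is indexed, including overlaps ("TATA" has sites at 1 and 3):
the transposon can use any of them and a total rule is simpler than an
arbitrary tie-break. Coordinates are BED 0-based half-open on disk and
1-based inclusive in memory; the conversion is an exact bijection
exercised by round-trip tests.

**Driver null.** Within a genome partition, insertions are assumed to
land uniformly over TA sites, giving gene *g* (footprint with
*t_g* TA sites) a Poisson expectation μ_g = λ·t_g with λ the partition's
insertions-per-TA rate. The upper tail P(X ≥ k_g | μ_g) is the per-gene
p-value. This operationalizes "more insertions than expected by chance"
with a single tunable background; it ignores chromatin accessibility,
replication timing, and expression-coupled targeting biases, which real
screens exhibit. It is also a *count* null, not a clustering statistic:
it does not reward tight spatial clustering of insertions within a gene
the way kernel-convolution common-insertion-site methods do.

**Partitions and the donor window.** SB re-integrates preferentially in
*cis* near its donor concatemer ("local hopping"). The donor chromosome
and the rest of the genome therefore get separate background rates, and
the elevated window itself is localized empirically: the donor
chromosome is cut into fixed-width bins (1 Mb by default; any width
consistent with the data's resolution works), each bin's count is tested
against the non-donor rate times its TA content (Poisson upper tail,
Bonferroni over bins), and the longest contiguous run of significant
bins is reported, leftmost on ties. Genes overlapping the window are
censored from the tested gene set — mirroring the practice of removing
such genes from driver output files — while the partition rate keeps all
insertions; this is conservative for the remaining donor-chromosome
genes because the window inflates the donor background estimate.

**Driver tiers.** Discovery uses all insertions with Benjamini–Hochberg
control at q < 0.5 (deliberately lenient, a screening list); progression
uses all insertions with Holm step-down FWER at 0.05; trunk restricts to
clonal insertions (read depth strictly above the cutoff) before testing,
also at Holm FWER 0.05. Holm was chosen over plain Bonferroni because it
is uniformly more powerful under the same FWER guarantee; Bonferroni is
available via `DriverConfig.fwer_method`. The recurrence condition
(≥ 3 tumors by default) is applied after adjustment, as a reporting
filter conjoined with significance rather than folded into the test.
Partitions are merged by keeping each gene's smaller adjusted p.

**Clonality.** The cutoff is the smallest whole read depth r such that
the fraction of the reference cohort's insertion records with depth > r
is at most 1 − percentile. Records at exactly the cutoff are subclonal
(strict ">", matching the ">299 reads" convention for a 300-read
cutoff). The published defaults are shipped as configuration — 300 reads
(top 5% of normal-skin depths) for deep bulk libraries, 200 reads
(top 30%) for shallower multi-region libraries — but the derivation is
always available from data and returns the exact bound, never a rounded
"nice" number. Replicate concordance uses Pearson and Spearman
correlations of log10(depth + 1) over shared sites (depths span five
orders of magnitude) plus the Jaccard of site sets.

**Orientation classes.** A driver's insertion pattern is classified from
its genic insertions: a two-sided exact binomial test of the sense-strand
fraction against 0.5, combined with positional clustering measured by the
IQR of the relative position along the gene. Significant sense excess
(p < 0.05) with clustering (IQR < 0.5) is the activating
promoter-fusion pattern; significant antisense excess, or dispersion
(IQR ≥ 0.5, evaluated with a 1e-9 float tolerance so an exactly uniform
spread counts as dispersed), is inactivating; fewer than 3 sites or any
other combination is indeterminate. The thresholds are exposed heuristics
(`min_sites`, `cluster_iqr`, `orientation_alpha`), not fitted values.

**Mutual exclusivity.** The statistic is the number of specimens altered
in both genes; the p-value is the lower-tail permutation probability
(1 + hits)/(1 + n_perm). Two nulls are provided. The default `swap` null
randomizes the whole specimen × gene matrix by checkerboard swaps,
preserving per-specimen burdens and per-gene frequencies, with
10 × (number of ones) swap attempts between recorded states (a numba
kernel keeps 10,000 permutations inside seconds). Note a structural
caveat: with only the two tested columns in the matrix, fixed row sums
freeze the pairwise overlap and the swap null is degenerate — it needs
the cohort's full alteration landscape to mix. The `permute` null
shuffles each gene's carrier set independently (column margins only);
its overlap null is exactly the 2×2-margin hypergeometric, which is what
the test suite enumerates against. For an isolated pair, use `permute`;
for a pair embedded in a cohort matrix, `swap` conditions on specimen
burdens as well.

**Multi-region heterogeneity.** Regions are reduced to a binary
gene × region incidence matrix at the regional clonal cutoff, rows with
no qualifying insertion dropped. Both axes are clustered with normalized
Hamming distance (fraction of mismatching entries — scale-free across
matrices) and Ward linkage. Ward presumes Euclidean geometry and Hamming
is not Euclidean in general; the combination is used deliberately to
mirror the analysis this package models, and merge heights should be
read as relative, not as variance decompositions. Trunk insertions are
those at the identical (chromosome, position, strand) nucleotide address
in every region of a mass; genes recurrently hit at *different*
addresses across regions are reported separately, since they indicate
independent targeting rather than shared clonal origin.

**Fusion reads.** Detection is exact-match at desk scale: a read is a
fusion call when it contains a configured splice-donor or splice-acceptor
motif and the k bases (default 20) flanking the junction match an exon
boundary of the supplied transcriptome uniquely. No spliced alignment is
performed — the scientific content (junction at an annotated exon
boundary; sense splice-donor fusions are promoter-driven activating
truncations, everything else inactivating) is preserved while remaining
fully oracle-verifiable. Orientation is the strand of the read on which
the junction matches, so reverse-complementing a read flips the label;
motif sequences are inputs, not constants. Expression contrasts consume
an already-normalized specimen × gene matrix (normalization is standard
upstream tooling) and report carrier/non-carrier group means and their
ratio, with a pseudo-count (smallest positive matrix value by default)
guarding zero denominators.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies
on: per-genome burdens from a negative binomial with mean 1,320 and
dispersion 3.5 — the dispersion chosen once so that cohorts of ~32
genomes span roughly 1–4,000 insertions, the heavy right tail reported
for SB-mobilized normal skin; uniform targeting of TA sites with a
multiplicative donor-window elevation; geometric subclonal depths
(mean 3) and log-normal clonal depths (median 10 × the 300-read cutoff,
σ = 0.5), so normals keep far fewer than 1% of insertions above the
cutoff while planted clonal sites essentially always exceed it; a small
passenger clonal fraction (2%) in tumors; activating drivers planted as
sense-strand clonal insertions clustered in a configurable 5' window of
the gene, inactivating drivers on both strands across the body.

It does *not* emulate: sequence realism (genomes are iid with a GC
dial), PCR/amplification depth artifacts, chromatin-biased targeting,
subclonal phylogenies beyond shared/private structure, or sequencing
error in RNA reads. Passing recovery tests therefore certifies the
statistical machinery under its own null — correct tail probabilities,
multiplicity control, window localization, and bookkeeping — not
robustness to the biases of real libraries.

Genome scale is deliberately reduced (defaults 5 × 1 Mb chromosomes with
200 × 10 kb genes; tests use 2–4 chromosomes of 150–250 kb). A
consequence worth knowing: with published-scale burdens on a small
genome, the per-gene background μ is orders of magnitude larger than in
a 2.5 Gb genome, so *discovery*-tier counts are not comparable to a real
screen's and planted-driver recovery is demonstrated primarily in trunk
mode, where the clonal depth filter restores a sparse background.

## Numerical and procedural choices

- Poisson tails via `scipy.stats.poisson.sf`, adjustments via
  `statsmodels.stats.multitest`; both are cross-checked against
  brute-force summation/threshold-scan oracles to 1e-12 in the suite.
- Genes with t_g = 0 (no TA sites) are untestable and receive p = 1.
- Driver results sort by (adjusted p, −k_g, gene id); collapse of
  duplicate insertion records keeps the strand of the deepest duplicate,
  '+' on ties; all tie-breaks are deterministic.
- The null-calibration test asserts the raw 5% level from inside
  [0.025, 0.05 + 3 SE]: a discrete Poisson null attains at most the
  nominal level, and the simulation is scaled (per-gene μ ≈ 10) so the
  attained level stays near 5% rather than collapsing.
- The checkerboard chain is a Markov chain started at the observed
  matrix; recorded states are dependent but the 10 × ones spacing gives
  adequate mixing for the matrix sizes used here (verified against the
  hypergeometric null on exchangeable fixtures).
- Simulation seeds are mandatory; identical (config, seed) produce
  byte-identical outputs, asserted by hashing in the suite.

## Known limitations

- The Poisson TA-count null is this package's own operationalization of
  driver enrichment; published driver lists computed with other
  statistics will not match count-for-count.
- Reproduction of the published cohort numbers requires the screen's
  supplementary insertion BEDs (not redistributable here); the dedicated
  test documents this and fails where the files are absent.
- `classify_orientation` needs several insertions per gene to say
  anything; single-insertion drivers are always indeterminate.
- The swap-null exclusivity test is only as good as the alteration
  matrix it is given (see the structural caveat above).
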