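# Methods

This note documents the models and procedures `germase` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Trio-lite haplotype construction

A biallelic SNP is *informative* when the fetus is heterozygous (0/1) and
the mother homozygous (0/0 or 1/1) with PASS filter status in both
individuals. Mother 0/0 implies the fetal ALT allele is paternal; mother
1/1 implies the fetal ALT allele is maternal. The rule is deterministic
given genotypes, so on error-free input parental assignment is exact —
which is what the round-trip tests against the trio simulator assert.

Discard rules and their bookkeeping: maternally heterozygous sites
(uninformative), indels and multi-allelic records (the rule is stated for
biallelic SNPs only), non-PASS calls in either individual ("high quality"
is operationalized as FILTER == PASS; re-scoring belongs to variant
calling, not here), and sites absent from the maternal table (treated as
non-informative — the handling of one-individual sites is genuinely open,
and this is the conservative choice). Every fetal-het site lands in
exactly one category, so the summary counts partition. Genuinely
contradictory genotypes (mother homozygous for an allele the fetus lacks)
are logged and excluded; they indicate genotyping error, not phase.

Coordinates are 1-based inclusive throughout, matching VCF and the printed
ICR windows.

## Allele-of-origin counting

A read is usable only if it maps uniquely against *both* parental
references; among usable reads the strictly smaller edit distance assigns
the parent, and ties are ambiguous. Ambiguous reads are dropped rather
than fractionally split: assignment is defined only on strict inequality,
and fractional splitting would break the integer count model the dropout
analysis relies on. Counts are raw reads, not TPM, so sampling effects and
dropout remain modellable.

Cell QC, in order: (1) ≥ 7500 expressed genes (inclusive boundary);
(2) exclusion of cells in the lowest quintile of allelic reads *or* of
SNP-containing genes — the union of the two exclusions. The quintile
boundary is the linear-interpolation 20th percentile; cells strictly below
it are removed and ties at the threshold kept, which makes the rule
deterministic and order-independent. Quintiles are computed over the
pooled dataset by default (per-donor pooling is a caller decision — pass
each donor's matrix separately). Note that a data-relative quantile filter
is inherently a single-application rule: re-running it on its own output
removes further cells, so the pipeline applies it once, after the
expression filter.

## Germ-cell staging

Expression is median-normalized per cell: values divided by the cell's
median over positive genes, rescaled by the global median of those medians
to preserve scale. Cells are clustered on 1 − Spearman correlation over
the marker panel (missing panel genes are dropped with a warning — real
panels routinely contain a few unexpressed markers). Linkage is
*average*, the standard companion to correlation distances; it is
configurable because the choice is not dictated by the method. The tree is
cut at k = 4 and clusters labelled from per-gene z-scored category means:
the cluster highest in somatic markers is somatic, highest in meiotic
markers MGC, highest in pluripotency + early-germ markers PGC, and the
remaining cluster LGC (for k ≠ 4 each cluster independently takes its
best-scoring stage). Automatic labelling replaces manual inspection for
reproducibility.

Tenfold enrichment: gene g is enriched in group A iff mean_A(g) ≥ 10 ×
mean_rest(g) and mean_A(g) > 0. The boundary is inclusive ("tenfold
higher" read inclusively) and a silent complement makes any expressed gene
enriched — the only convention under which a zero denominator is defined.

## Imprinting and the dropout null

The expected-allele ratio of a (cell, gene) is reads from the allele
predicted by imprinting over all allelic reads; 1 means fully imprinted
expression, 0.5 biallelic (erased). Only *confirmed* imprinted genes enter
tests; predicted/provisional categories are excluded, since they do not
behave imprinted even in somatic cells. Ratios aggregate per imprinted
gene-cluster (each controlled by one ICR, erasing as a unit) with medians
as the headline statistic.

Allelic dropout makes a single monoallelic observation uninformative. The
null: dropout reveals either allele with probability ½ independently per
cell, so n cells all showing the *specific expected* allele has
p = (½)ⁿ, one-sided toward the expected allele. At α = 0.05 the
significance boundary is n = 5 ((½)⁵ = 0.031 < 0.05 < 0.0625 = (½)⁴) —
this is the unique reading under which five cells are the boundary. A cell
counts as monoallelic when its ratio is exactly 1 with ≥ 1 read
(configurable minimum; no stricter published convention exists). The
implementation is verified against exhaustive enumeration of all 2ⁿ
dropout outcomes for n ≤ 12.

Group comparisons use the one-sided Mann–Whitney–Wilcoxon test: exact
enumeration when both groups have ≤ 8 observations and no ties, otherwise
the normal approximation with tie correction.

## X-reactivation classification

**Scalar.** Per (cell, chromosome), maternal and paternal reads of
SNP-containing genes are summed; on the X, known XCI escapees are excluded
first (they stay biallelic on an inactive X and would dilute the signal).
The scalar is the max-allele fraction bias = max(M, P)/(M + P) ∈ [0.5, 1]
— the minimal symmetric choice that makes the autosomal null one-sided and
direction-free. Parental direction is reported separately as the paternal
fraction, and the presumed active X is simply the parent with more summed
reads.

**Null.** Allelic bias of a sum shrinks with depth, so chromosomes are
binned by total allelic reads with boundaries placed so each bin carries
an equal share of reads (4 bins by default; configurable — published bin
counts exist only for pooled gene-level analyses). Bin edges are computed
over distinct total values; points equal to an edge fall in the lower bin,
so equal totals always share a bin, and at least n_bins distinct totals
are required. Per bin, the interval containing 95% of *autosomal* biases
(linear-interpolation empirical quantiles at 2.5/97.5%) defines the
biallelic range; the X never shapes its own null. Bins with < 20 autosome
points trigger a warning. Held-out points with totals outside the training
range go to the nearest boundary bin, logged.

**Call.** An assessable X (≥ 3 proper SNP-containing genes and ≥ 33
allelic reads, both inclusive; the read minimum refers to proper-X allelic
reads) is XiXa_biased iff its bias lies strictly above its bin's upper
bound — only the upper tail indicates monoallelic expression since the
scalar is folded at 0.5. This makes the false-positive rate conservative:
the 95% interval leaves 2.5% in the upper tail. Increasing a cell's bias
can never flip a biased call back into range.

**Geometric-mean variant.** Per gene, bias is computed with a +1
pseudocount on both alleles, (max(m, p) + 1)/(m + p + 2), then the
geometric mean over a chromosome's genes is compared against a 99%
autosomal interval built with the same binning. The pseudocount shrinks
low-coverage genes toward 0.5, making the statistic robust to
dropout-driven outliers; the exact formula is a design choice of this
package (the metric is named in the literature but not specified) and is
parameterized.

**Median-bias classifier.** For datasets with too few genes per cell for
chromosome sums, a cell is in XCI state iff the median per-gene
monoallelic bias over proper X genes is ≥ 0.95 (inclusive).

**Differential expression.** XiXa vs XaXa contrasts use a per-gene
negative-binomial GLM (log link) with dispersion estimated by method of
moments within groups and floored at Poisson — the distribution family is
the method's requirement, the moment estimator the simplest consistent
choice at these sample sizes. P-values are Wald; genes with all-zero
counts are skipped. Benjamini–Hochberg adjustment runs across tested
genes, and `significant` refers to q < 0.05; both raw p and q are
reported, since published significance statements mix the two.

## Methylation summaries

Windows are 1-based inclusive (printed hg19 ICR coordinates are used
as-is; `.bed` input is converted from 0-based half-open with the
conversion documented in the reader). The region rate is the mean of 0/1
CpG calls inside the window, with SD across sample groups when a grouping
is provided and per-allele rates when reads carry allele tags. Pattern
counting emits one string per read over the window's CpG sites in
coordinate order, with a placeholder for sites a read does not cover, so
counts are total. SNP-allele splitting keeps alleles with frequency
strictly above 5% and pools the rest as "other"; subsets are disjoint and
cover all reads observed at the SNP.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the pipeline assumes:

- trio genotypes with Mendelian-consistent fetal calls, a configurable
  informative-site yield (defaults: 15% fetal het, 70% maternal hom —
  exome-trio scale), plus injected indels, low-quality records, missing
  maternal sites and rare genotype errors (0.2%) so the discard paths are
  exercised;
- per-gene totals that are negative binomial (dispersion 1 by default)
  scaled by per-cell depth — the sparse, overdispersed counts the quintile
  filters assume;
- autosomal biallelic sampling Binomial(n, 0.5); per-cell X state with the
  active parent chosen at random; XiXa cells emitting residual
  inactive-allele reads at a 2% leak (x_bias = 0.98) rather than strictly
  zero, because real reactivation is partial and the classifier must be
  tested off the degenerate case; escapees biallelic regardless of X
  state; imprinted clusters erasing as a unit with probability
  erasure_fraction per germ cell;
- dropout reassigning all of a gene's reads to one allele (chosen at the
  gene's underlying allelic probability — a fair coin for biallelic
  genes, which is exactly the dropout null), preserving the drawn total;
- stage archetypes with geometrically graded category profiles and fixed
  per-gene factors, separable by rank-based clustering;
- methylation reads with independent per-CpG calls at per-allele rates.

Not emulated: alignment artifacts, mapping bias toward the reference
allele, gene length/GC effects, doublets, batch effects, developmental
trajectories between stages, or linkage between neighbouring SNPs. Passing
tests therefore demonstrate correctness of the *inference machinery* under
the stated statistical model, not robustness to every artifact of real
libraries.

Determinism: every generator takes a seed and fixed seeds give
byte-identical output; truth labels ship with every simulated object so
acceptance tests are parameter-recovery tests.

## Calibration and problem sizes

Split-half calibration (`germase.calibration`) simulates 400 cells × 22
autosomes per seed (negative-binomial chromosome totals, mean 200,
dispersion 1, split multinomially over 6 genes per chromosome so the same
draw serves both the chromosome-sum and gene-level GM statistics), builds
each null on 200 cells and measures held-out coverage on the other 200,
averaged over 10 seeds. Observed coverage of the 95% bias interval runs
slightly above nominal (≈ 96%): at the low-read end the bias statistic is
discrete, and inclusive interval bounds absorb whole atoms of its
distribution. This conservatism is inherent to empirical intervals on
discrete statistics, not a tuning artifact. The GM statistic is nearly
continuous and its 99% interval calibrates to within a few tenths of a
point. Recovery tests use 120–200 cells with ~70 genes; the full suite
and the acceptance script each run in seconds on one core.

## Known limitations

- The edit-distance read assigner consumes alignment summaries
  (uniqueness flags and edit distances); producing them from FASTQs is
  alignment work outside this package.
- The NB Wald test is asymptotic; at very small group sizes an exact or
  permutation test would be preferable.
- The quintile filter's pooled default can remove a whole low-depth donor;
  pass per-donor matrices when donors differ strongly in depth.
- Stage labelling assumes the panel's category structure is informative
  for the dataset; a panel without somatic markers cannot separate soma.
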