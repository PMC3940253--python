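# Methods

`dexsea` implements a comparative-transcriptomics pipeline for small
two-genotype (transgenic vs wildtype), two-tissue (blood vs cerebellum)
expression studies, validated end to end on synthetic data with planted
ground truth. This note records the statistical model behind each stage,
the defaults and why they were chosen, and what the synthetic validation
does and does not demonstrate.

## Normalization

Input matrices are linear-scale intensities (genes x samples); they are
log2-transformed as log2(x + 1) and quantile-normalized across samples:
every column is replaced by the mean order-statistic vector, so all sample
distributions coincide exactly afterwards. Tied values within a sample
receive the mean of the reference values at their tied ranks — the
standard convention, which makes the map well defined and idempotent. The
algorithm is the usual probe-level quantile method applied at the
gene/probe-set matrix level, since probe-level summarization (PLIER, RMA)
is outside this package's scope; with intensities already summarized the
two placements are equivalent in effect for downstream statistics.

## Per-gene differential expression

Each gene is fitted by ordinary least squares with

    y = b0 + b1 * tissue + b2 * genotype,

tissue coded blood=0 / cerebellum=1 and genotype wildtype=0 /
transgenic=1, so b2 > 0 means up-regulation in transgenic animals. No
interaction term is included: with 3–5 replicates per cell the additive
model is the highest resolution the design supports. Two-sided p-values
for b1 and b2 come from the t distribution with n − 3 residual degrees of
freedom. Genes fitted exactly (residual variance < 1e-12) are assigned
p = 1 when the coefficient is also ~0 and p = 0 otherwise, with a logged
warning — an arbitrary but explicit convention for a degenerate case that
arises only in synthetic or duplicated data.

Signed fold changes are computed from per-genotype linear-scale means:
transgenic/wildtype when transgenic is higher, −(wildtype/transgenic)
otherwise, so magnitudes are always ≥ 1 and negative values mean
down-regulation in transgenic animals.

The default significance threshold is uncorrected p < 0.01 (configurable).
FDR is reported alongside via Storey–Tibshirani q-values: the null
proportion π0 is estimated from π0(λ) = #{p > λ}/(m(1 − λ)) on
λ ∈ {0, 0.05, …, 0.90}, smoothed with a cubic least-squares polynomial
evaluated at λ = 0.90 and clipped to (0, 1]. (The reference R
implementation uses a df-3 smoothing spline; a cubic polynomial fit is its
deterministic, dependency-free equivalent on this 19-point grid.) Then
q_i = min over thresholds t ≥ p_(i) of π0·m·t / #{p ≤ t}, which is
monotone in p by construction and reduces exactly to Benjamini–Hochberg
when π0 = 1. Below 100 tests the π0 smoother is unreliable, so the
estimate falls back to π0 = 1 with a warning.

Welch's unequal-variance t-test (with Welch–Satterthwaite degrees of
freedom) is provided for post-hoc two-group comparisons within a tissue
stratum.

## Gene-set enrichment

Designed for studies too small for phenotype-label permutation, the test
keeps the ranking fixed and permutes gene sets:

1. **Ranking.** Genes are ranked by signal-to-noise within one tissue:
   (mean_tg − mean_wt)/(sd_tg + sd_wt). Each group sd is floored at
   max(sd, 0.2·|group mean|, 1e-8) so constant genes cannot yield infinite
   metrics; 0.2 is the floor conventional in GSEA implementations. Ties
   keep input gene order (stable sort), making results deterministic.
2. **Enrichment score.** A running sum over the ranked list rises by 1/Nh
   at set members and falls by 1/(N − Nh) elsewhere (unweighted
   increments; a weighting exponent is deliberately not applied — the
   statistic is the classic Kolmogorov–Smirnov-style form). The increments
   are balanced, so the sum always returns to zero. ES is the signed
   maximum deviation from zero — not the literal maximum, which could
   never be negative and thus could not express depletion (negative NES).
   An exact tie between the positive and negative extremum resolves to the
   positive one. The leading edge is the members at or before the maximum
   (in rank order) for ES > 0, or at or after the minimum (in reverse rank
   order) for ES < 0.
3. **Null distribution.** For each distinct set size s, 2,000 random
   gene subsets of size s are scored on the same ranking (drawn uniformly
   without replacement; one seeded generator per run; the null is cached
   and shared by all sets of equal size). The permutation p-value is the
   two-sided magnitude test max(#{|null ES| ≥ |ES|}, 1)/n_draws, so the
   smallest attainable p at 2,000 draws is 0.0005 and the p-value of a
   random set is exactly uniform. (Counting only same-sign draws against
   the full-draw denominator would double the type-I rate under a
   sign-symmetric null; restricting the denominator to same-sign draws
   would instead raise the attainable floor above 1/n_draws. The
   two-sided count is the only convention that keeps both the floor and
   the calibration.) ES = 0 gives p = 1.
   Internally the null is evaluated in closed form from sorted hit
   positions (the running-sum extrema can only occur adjacent to hits),
   which is algebraically identical to the explicit walk and ~100x faster.
4. **NES and FDR.** NES = ES / mean |null ES of the same sign|, computed
   per sign because the gene-set null need not be symmetric. For FDR, every
   null draw is normalized by its own distribution's same-sign mean and
   pooled; a set's q is the ratio of same-sign tail fractions (pooled null
   vs observed NES), clipped to [0, 1] and made monotone non-increasing in
   |NES| within each sign by taking, for each set, the smallest raw
   estimate among equally or less extreme sets — the same suffix-minimum
   device Benjamini–Hochberg uses. Whether to normalize per sign or pooled
   is a genuine convention choice; per-sign is used here and matters only
   for strongly asymmetric rankings.

Sets are size-filtered to 15–500 members *after* intersection with the
measured genes, since the statistic only ever sees measured genes.

## Candidate-gene overlap

Overlap between a differential list and a candidate list is tested with
the exact upper-tail hypergeometric probability P(X ≥ k). The universe is
the set of measured genes after filtering, not the genome — the standard
choice that conditions on what the platform could have detected. Both
lists are intersected with the universe first. Homolog translation
(e.g. mouse to human) is a static two-column table applied before testing;
one-to-many mappings expand and de-duplicate, unmapped ids are dropped
with a logged count.

## Clustering

Significant genes are standardized per row (mean 0, sd 1, n−1
denominator), then transcripts and samples are clustered agglomeratively
with distance 1 − Pearson correlation and average linkage — the standard
expression-heatmap recipe; euclidean distance and complete/single linkage
are exposed as options. Rows/columns that are constant after
standardization have undefined correlation and are excluded with a
warning. Cutting the sample dendrogram at 2 and 4 clusters tests whether
samples separate by tissue and then by tissue x genotype; separation is
"exact" when clusters and factor levels are in bijection.

## Synthetic data

The generator emulates a small paired-design microarray study. On the log2
scale, each gene's value is

    baseline + tissue_effect·[cerebellum] + genotype_effect·[transgenic] + noise,

exported as linear intensities (2^x). Defaults: 10,000 genes; 5 replicates
per tissue x genotype cell (a 5 KO vs 5 WT design; the analysis scripts
also use 3 vs 3); baseline ~ N(8, 2) log2, typical of microarray
intensities; tissue effects ~ N(0, 1.0 log2) on 70% of genes; 50
individually responsive genes at ±1.0 log2; i.i.d. Gaussian noise with
sd 0.5 log2, a realistic replicate-to-replicate spread for arrays. The
magnitudes of tissue and genotype effects in the motivating data are not
known, so these defaults are explicit stand-ins, exposed in the
configuration.

Planted pathways add a coherent shift (the configured value, applied
identically to every member, so "mean member shift" is exact) to members
drawn from non-responsive genes — or to explicitly pinned member ids, which
lets several datasets perturb one shared pathway definition. Background
sets draw members uniformly; overlap between sets is allowed, as in real
pathway databases. When a tissue-flat fraction of responsive genes is
requested, the remaining responsive genes receive a guaranteed-nonzero
tissue effect (magnitude ≥ half the tissue sd) so the planted fraction is
recoverable rather than blurred by near-zero draws.

What the generator does **not** model: probe-level effects and
summarization, batch/array effects, intensity-dependent variance,
correlated genes outside planted sets, and RNA-seq count noise. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the stated model, not that any biological conclusion
transfers to a particular real dataset.

## Problem sizes used in validation

The test suite and the acceptance script validate at deliberately modest
scale: null calibration at 5,000 genes (Kolmogorov–Smirnov distance of DE
p-values from uniform, and the fraction of 50 random sets at permutation
p < 0.05 against its 99% binomial band); power at 2,000 genes with a
50-gene pathway shifted +1 log2 against noise sd 0.5 over 20 seeded
replicates; the analysis scripts at 4,000 genes and 42 sets. These sizes
give stable Monte-Carlo estimates while keeping a full run in minutes;
the algorithms are vectorized and scale linearly in genes x draws.

## Reproducibility

All randomness flows from integer seeds through `numpy`'s PCG64
generator. The pipeline fans its single seed out to per-stage child seeds
by fixed offsets, so stages can be reproduced in isolation; rerunning any
stage or the full pipeline with the same inputs and seed is byte-identical
(floats are written with 17 significant digits, enough to round-trip
exactly).

## Known limitations

- The per-gene model is plain OLS; no empirical-Bayes variance moderation
  (limma-style), so per-gene power at n = 3 per cell is modest. This is by
  design: the pathway statistic, not the per-gene test, carries the
  inferential weight at these sample sizes.
- Gene-set permutation answers a different null than phenotype
  permutation (random gene sets vs no genotype association); its p-values
  are well calibrated against the former and anticonservative against the
  latter when genes are strongly co-expressed.
- π0 estimation is unstable for small m and intentionally falls back to
  the conservative π0 = 1.
- The q-value/FDR machinery assumes many tests; with very few gene sets
  the pooled-null FDR is coarse (granularity 1/(n_sets · n_draws)).
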