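# Methods

## Preprocessing

Input is a gene × sample matrix of non-negative expression values (TPM or
comparable). Three steps, in order:

1. **Depth filter.** Samples whose total estimated counts fall below
   `min_total_counts` (default 10⁶) are removed; the filter only runs when
   per-sample totals are supplied. Removing every sample is an error.
2. **Quantile normalization.** The reference distribution is the
   across-sample mean of order statistics. Tied values within a column
   receive the mean of the reference values over their tied rank span —
   the conventional tie policy of quantile-normalization implementations.
   Output columns are exact multiset permutations of one another.
3. **Log transform.** `log2(x + pseudo_count)` with pseudo-count 4 by
   default. The pseudo-count damps the variance of lowly expressed genes
   before correlation.

Correlations are Pearson, computed on the logged matrix across samples.
A zero-variance gene has no defined correlation; rather than propagate
NaN silently into ranked lists, the correlation step raises an error that
names the offending genes so the caller drops them deliberately. The
sample dendrogram is UPGMA (average linkage) on the distance
1 − Pearson(sample profiles) — the distance is chosen for consistency
with the gene-side machinery — and serializes to Newick with half-height
branch lengths (ultrametric leaves).

## Ranked lists and ORA

For target gene *t*, all other genes are sorted by decreasing correlation;
ties break lexicographically by gene id so the list is identical across
platforms and runs. The ORA background is exactly the sampling frame of
that list: the n measured genes minus the target. The target is likewise
excluded from pathway membership, keeping the 2×2 margins consistent.
The one-sided ("greater") Fisher p-value is the hypergeometric upper
tail, computed by an exact integer term recurrence with a single rational
division at the end — no log-space accumulation error. Depletion is not
tested. No multiple-testing correction is applied anywhere: pathways are
*ranked* by raw p-values, never thresholded for significance.

Pathway size filtering (default 15–500) is applied to the *effective*
size |members ∩ universe|, i.e. after restricting to measured genes —
downstream statistics only ever see measurable genes, so filtering on raw
annotation sizes would make the bounds depend on annotation coverage.

## Unweighted GSEA with exact p-values

All running sums are kept in rescaled integers: a member contributes
+(n−m), a non-member −m, so the true running sum is integer/(m(n−m)) and
the total is exactly 0. ES is the signed maximum |prefix|; the argmax is
the earliest position attaining it. When the maximum magnitude is reached
by both a positive and a negative prefix, the sign resolves to +1: the
argmax is ambiguous under ties, and the method's stated focus is
detection of top-of-list enrichment.

The null places the m members uniformly at random among the n positions.
The p-value for a positive ES with integer numerator T is
Pr(max prefix ≥ T) = 1 − A/C(n, m), where A counts arrangements whose
every prefix stays ≤ T−1. A is computed by the lattice-path DP
f[j][h] = [h(n−m) − (j−h)m ≤ T−1]·(f[j−1][h−1] + f[j−1][h]) with two
rolling rows of Python big integers — O(n·m) time, O(m) memory, exact.
The null statistic is the *unconditional* maximum prefix over all
arrangements (every arrangement has max prefix ≥ 0, so conditioning on
positive-ES arrangements would change nothing for T > 0; for T ≤ 0 the
p-value is defined as 1, matching the non-positive-ES convention).
Pathways with ES ≤ 0 always receive p = 1.

DP results are memoized on (n, m, T), which pays off in corpus runs where
many genes share a pathway's (n, m).

## Percentile (p-)scores

A pathway whose members are internally correlated inflates enrichment
statistics for *all* genes: a non-member gene correlated with the module's
shared factor sees the whole block crowd the top of its ranked list. The
p-score removes this by calibrating per pathway against the *observed* ES
distribution: pool the pathway's ES across every target gene in the
corpus, fit a Gaussian KDE, and report the survival probability
Pr(ES ≥ ES_e). Because the KDE is a Gaussian mixture, the survival is
evaluated in closed form as the mean of normal survival functions — exact
and faster than quadrature (agreement with adaptive quadrature is tested
to 1e−8).

Bandwidth is Silverman's rule of thumb, h = 0.9·min(sd, IQR/1.34)·N^(−1/5)
with sample sd and type-7 quartiles — the long-standing default of
standard statistical environments. If the IQR is zero but the spread is
not, the sd term alone is used; an all-identical distribution is an error.
Member genes' ES values are *included* in the observed distribution by
default (the corpus pools every ranked list); `exclude_members_from_kde`
is available, and matters only when members are a non-trivial fraction of
the corpus.

A structural property worth knowing: ES is a maximum-deviation statistic,
so |ES| is bounded away from 0 (typical floor ≈ √(1/m)), and a pathway's
observed ES distribution is bimodal with a hole around 0. The survival
transform therefore maps no gene into one band of (0, 1): non-member
p-scores have mean ≈ 0.5 and nearly identical distributions across
pathways of very different internal correlation — the calibration the
score exists for — but they are not decile-uniform, and the tests check
mean calibration and cross-pathway similarity rather than uniformity.

## Ranking and evaluation

The per-gene pathway table carries ORA p per threshold, ES, exact GSEA p,
p-score, and a final rank under the combined key: ORA top-500 p ascending,
then p-score ascending, then set id. Pathways with no ORA signal all sit
at p = 1, and the p-score orders them — the gap the percentile
calibration fills. The ranking is total, deterministic, and invariant to
input order.

Evaluation labels each (gene, pathway) pair condition-positive iff the
gene is an annotated member. ROC curves sweep thresholds over scores
pooled across genes (per-gene averaging of curves would weight genes with
few annotations equally with heavily annotated ones; pooling was chosen
and is the only mode offered); AUC is trapezoidal, so tied scores
contribute half weight and all-tied scores give exactly 0.5 (verified
against the Mann–Whitney pairwise formulation). Two scoring modes exist:
pooled p-values, and per-gene pathway ranks (rank 1 strongest, pooled
across genes). The inflation diagnostic computes, per pathway, the mean
of −log₁₀ p over non-member genes, and summarizes each approach by the
Pearson r of that mean against internal correlation (the mean pairwise
member correlation); a zero-variance side reports an explicit undefined
marker rather than NaN.

## Synthetic corpora

The generator draws genes from a multivariate normal with
block-exchangeable covariance: planted pathway blocks with within-block
correlation ρ_p, background/cross-block correlation ρ0 (default 0),
realized by the factor construction
√ρ0·w + √(ρ_p−ρ0)·f_block + √(1−ρ_p)·ε, which is positive semi-definite
exactly when ρ0 ≤ ρ_p < 1 (violations are rejected before sampling).
Values are mapped to an expression-like scale as max(0, 10 + 2·z) —
baseline 10, noise sd 2, keeping flooring a >5σ event — so quantile
normalization and log2(x+4) operate on realistic magnitudes. The planted
blocks are emitted as a truth GMT. Every dataset is byte-reproducible
from (config, seed).

What the generator emulates is the *correlation structure* a compendium
induces — a tunable internal correlation per pathway, which is precisely
the quantity the diagnostics measure. It does not emulate count-level
RNA-seq realism (negative-binomial dispersion, library-size variation,
batch structure), tissue-driven sample clustering, or overlapping pathway
membership; passing tests therefore demonstrate the statistical machinery
and its calibration, not robustness to those data features.

## Study designs and problem sizes

Two canned studies (module `studies`) back the property-level claims:

- **Parameter recovery:** 1000 genes × 50 samples, one 30-gene pathway at
  ρ = 0.7 planted among nine same-size decoy blocks at background
  correlation (real competitors make rank 1 non-trivial), 20 seeds; the
  combined ranking places the planted pathway first for ≥ 90% of member
  genes (observed: 100%).
- **Inflation/calibration:** 300 genes × 50 samples, two 20-gene pathways
  at ρ = 0.8 vs 0.1, 20 seeds; mean non-member −log₁₀ GSEA p is strictly
  larger for the high-ρ pathway in every seed, while both pathways'
  non-member mean p-scores stay in [0.4, 0.6].

These sizes keep a full study within a couple of minutes on one CPU while
leaving the contrasts far from their thresholds. `scripts/acceptance.py`
re-runs both studies plus a six-level internal-correlation gradient
(400 genes, pathways at ρ = 0 … 0.75) whose inflation summary r is
strongly positive for both GSEA and ORA.

## Numerical choices and edge cases

- Exact integer arithmetic wherever a p-value is exact by construction
  (hypergeometric tails, the DP); floats appear only at the final
  division.
- Ranked-list and ranking tie-breaks are lexicographic by gene/set id —
  reproducibility across platforms.
- Thresholds exceeding the ranked-list length are rejected (`ora_profile`)
  or dropped (`analyze_corpus`, which adapts the scan to corpus size).
- Correlation matrices are symmetrized and clipped to [−1, 1] after
  `np.corrcoef` to absorb last-ulp rounding.
- Degenerate inputs error loudly: empty universes, zero-variance genes,
  all-identical ES distributions, single-class ROC labels, infeasible
  covariances.
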