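# Methods

`mirrank` implements an offline, testable version of a miRNA prioritization
workflow used in endurance-exercise cardiology: candidate circulating miRNAs
are scored by how many of their predicted target genes fall into
cardiovascular-relevant gene sets, ranked by natural-breaks clustering of
those counts, characterized by over-representation analysis, and finally a
selected panel is analyzed in a paired pre/post qPCR cohort with
nonparametric statistics.  Because the original workflow depended on live
database queries (multi-database target predictors, gene-disease and
tissue-expression services, a remote enrichment API) and on unpublished
subject-level data, every input here is either a flat file or a synthetic
dataset with planted ground truth.

## Category gene sets (`gene_sets`)

Three filters, all with inclusive (`>=`) thresholds:

* **Process sets.** A gene joins a category (angiogenesis, cardiac muscle
  functions, coagulation, fibrosis, hemopoiesis, inflammation, muscle
  hypertrophy, platelet activity) when any category keyword occurs,
  case-insensitively, in the name of any GO-style term annotating it.
  Substring matching is the default because it is the weakest assumption
  about how term names embed keywords; a whole-word mode is available.  The
  shipped keyword lists are simply the category names (with spelling
  variants for hemopoiesis); they are configuration, not biology, and are
  meant to be overridden.
* **Disease set.** A gene is disease-associated when it has >= 5
  disease-linked publications OR >= 3 disease-associated variants
  (DisgeNET-style evidence counts).  The disease set is used as one more
  ranking category alongside the process and tissue sets.
* **Tissue set.** A gene qualifies when some record shows expression
  confidence >= 1 (on the 0–5 TISSUES-style scale) in one of 14
  cardiac-centric tissues/cell types (Atrium … Pericyte).  Unknown tissue
  names are ignored rather than rejected, since real exports mix organs.

All filters are idempotent and monotone in their thresholds; gene symbols
are uppercased and trimmed on ingest, and cross-namespace ID mapping is out
of scope (inputs must share one symbol namespace).

## Target filtering and aggregation (`targets`)

Stem-loop identifiers are expanded to {stem-loop, -3p, -5p} before
prediction lookup, because target predictions are arm-specific.  Within
each database the best-scoring `ceil(f·n)` predictions are retained
(default f = 0.10, the top decile), honouring a per-database score
orientation flag since sources disagree on whether higher or lower is
stronger.  Records tied at the boundary score are all retained — this makes
the filter deterministic and row-order independent, at the cost of
occasionally keeping slightly more than `f·n`.  Per-database cutting is the
default (pooled mode by flag) because native score scales are not
comparable across sources.  Aggregation merges arm-expanded variants back
under the queried stem-loop id, records per-arm provenance, and reports per
gene the *support* — the number of distinct databases predicting the pair.
`min_support` defaults to 1 and exists for sensitivity analysis.

## Ranking (`ranking`)

Cell (m, c) of the count matrix is |targets(m) ∩ genes(c)|.  Each category
column is classified into at most k = 4 clusters by exact Fisher–Jenks
optimization: the contiguous partition of the sorted counts minimizing
total within-class sum of squared deviations, found by an O(k·m²) dynamic
program over runs of equal values with weighted prefix sums.  Working over
runs keeps duplicates in the class statistics while guaranteeing equal
counts share a label and that k exceeding the number of distinct values
collapses gracefully; for tie-free data this equals the unrestricted
optimum, which the test suite verifies against exhaustive enumeration of
all contiguous partitions for n <= 12.  Labels are 1 (lowest counts) to k;
classifying each column independently is the default, with a pooled mode
for a shared break scale.

The composite score is the plain sum of per-category labels — the simplest
monotone aggregation of cluster membership — with ties broken by total
target count and then miRNA id; `rank` is the dense rank of the composite.
The sorted counts+labels matrix is exported as a TSV that round-trips
through the module's reader and imports into matrix-heatmap viewers.

## Enrichment (`enrichment`)

A local one-sided hypergeometric over-representation analysis replaces any
remote enrichment service: for a query of n genes in a universe of N, a
term covering K genes with overlap k gets p = P[X >= k],
X ~ Hypergeometric(N, K, n), computed in log space (log-gamma +
log-sum-exp) for stability and verified against exact rational-arithmetic
summation to 1e-10.  The universe defaults to the union of the library's
genes and is overridable; query genes outside it are dropped with a
warning; terms with zero overlap are excluded before FDR adjustment.
Benjamini–Hochberg q-values are computed per library (statsmodels step-up),
significance is q < 0.05, and significant terms across queries are
summarized as a binary term × miRNA matrix with a margin column, sorted by
margin.  The odds ratio uses a 0.5 continuity correction when any
contingency cell is zero.  This ORA is a deliberate, documented departure
from combined-score enrichment statistics: deterministic and exactly
testable.

## qPCR statistics (`qpcr_stats`)

Expression is `2^-dCT` with `dCT = mean(CT) − mean(spike CT)` over up to
three replicates per channel; `log_expr = −dCT` (log base 2, chosen for
fold-change readability).  A sample missing all miRNA replicates is
non-detectable and excluded downstream; a missing spike-in normalizer is an
error.  CT values must lie in (0, 45).

The tests are exact in the regimes small cohorts actually occupy:

* **Wilcoxon signed-rank** (paired pre/post): zeros dropped, mid-ranks on
  |d|; for n <= 20 the null is the distribution of W+ over all 2^n sign
  patterns, computed by convolution over the doubled mid-ranks; above that
  a tie-corrected normal approximation (no continuity correction, matching
  mainstream statistical packages' drop-zeros default).
* **Mann–Whitney** (subgroup splits): exact over all C(n_a+n_b, n_a)
  labelings for n_a+n_b <= 16, tie-corrected normal approximation
  otherwise.  Dichotomization uses inclusive lower groups (value <=
  threshold), matching the clinical cutoffs the workflow uses (hs-CRP
  <= 5 mg/dL, lactate <= 4 mmol/L, race time 10 h).
* **Spearman**: Pearson correlation of mid-ranks; exact permutation null
  for n <= 8, t approximation above.

Two-sided p-values are twice the smaller tail, capped at 1.  Note the
signed-rank test is *not* invariant under nonlinear monotone transforms
(it ranks difference magnitudes), but it is invariant under positive
rescaling — which is exactly why the choice of log base is immaterial; the
purely rank-based Mann–Whitney and Spearman are invariant between the
`2^-dCT` and log scales outright, and the test suite asserts these
properties.  A Shapiro–Wilk gate (`choose_location_test`) is provided for
biomarker summaries, but the miRNA pipeline always uses the nonparametric
battery.

## Synthetic data (`synthetic_data`)

The generator emulates the study conditions rather than real database
content: 55 input miRNAs, 14 prediction databases with i.i.d. continuous
uniform scores (so the true top decile is ties-free and known per row),
annotation tables whose category/disease/tissue truth is planted by
construction, 50-term libraries with one planted term oversampled into the
query (default 60% of a 60-gene query), and 23-subject paired cohorts.
Cohort CT values use a per-(subject, miRNA) latent baseline (SD 1.0 cycle)
shared between timepoints, a post-run shift of −log2(fold change) (default
plant: 2.0 on hsa-miR-126), triplicate noise of SD 0.15 cycles, and a
stable spike-in at 22 cycles; these noise scales keep the paired test
well-powered at n = 23 for a two-fold change, mirroring the sensitivity of
the emulated assay.  A planted Spearman correlation (default −0.632
between hsa-miR-1-3p log-expression and post-run hs-CRP) is achieved by
drawing the miRNA's latent and the biomarker's Gaussian-copula latent
bivariate normal with Pearson parameter r = 2·sin(π·ρ_S/6), the exact
Gaussian-copula relation, then mapping the biomarker latent through a
log-normal (hs-CRP, hs-TnT) or normal (glucose, lactate, race time)
margin whose location sits near typical post-ultramarathon values
(cosmetic realism; never asserted in tests).

What the generator does **not** emulate: real prediction-score
distributions and their inter-database correlations, GO graph structure,
within-subject biomarker trajectories, pre/post biomarker correlation, or
dropout/missingness patterns.  Passing tests therefore demonstrate that the
pipeline's logic recovers known truth under clean, correctly specified
conditions — not that it would reproduce any particular published cohort's
p-values, which depend on unpublished subject-level data.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for
desk-scale runs: enumeration oracles at n <= 12 (Jenks), n <= 8/12
(signed-rank / Mann–Whitney), an exhaustive-in-k hypergeometric grid with N
up to 200, 200 library replicates for planted-term recovery, 1,000 null
cohorts at n = 23 for type-I calibration, and n = 2,000 cohorts for
fold-change and copula recovery.  Degenerate inputs are handled
conservatively: all-zero paired differences report p = 1 with a warning,
constant ranking columns label everything 1, empty splits and constant
correlation vectors raise errors rather than returning NaNs.

## Known limitations

* Keyword screening sees only term names, not definitions or the GO graph;
  ancestor propagation is out of scope.
* The ORA is not a reimplementation of any specific enrichment service's
  ranking statistic; comparisons to such services are qualitative.
* The exact Mann–Whitney enumerates labelings combinatorially; above 16
  total observations it switches to the normal approximation, which is
  slightly conservative near ties.
* Arm-level provenance is tracked, but expression of a stem-loop query is
  not apportioned between arms (the aggregation counts distinct databases,
  not distinct arms).
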