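# Methods

This note records the statistical models behind `germcore`, the
defaults that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Data model and cleaning

A phenotype table is a rectangular accession × trait grid. Every trait
is declared quantitative (finite real, optional units) or qualitative
(level from an ordered vocabulary); missingness is explicit per cell.

Redundancy is defined as exact equality of the full value vector,
missingness pattern included — duplicated records in a genebank arise
from duplicated passport entries, not from two accessions measuring
identically by chance, so no numeric tolerance is applied. One member
per redundancy group survives, chosen by a seeded uniform draw
(default seed 0) so repeated runs agree. The missing-rate trait filter
is strict: a trait is retained iff its missing fraction is **below**
the threshold (default 0.30), so a trait missing exactly 30% of cells
is dropped while 26.5% survives. Filtering runs after redundancy
removal by default; the CLI exposes the reverse order.

## Multiple imputation by chained equations

Missing cells are filled one trait at a time, conditioning on all other
traits, visiting traits in ascending missing-rate order so each model
conditions on the most complete data available.

* **Quantitative traits** — predictive mean matching (PMM): a ridge-
  stabilised linear regression on all other traits (qualitative
  predictors reference-coded) yields a posterior draw of (β, σ²)
  (σ² from a scaled inverse-chi-squared on the residual degrees of
  freedom, β from its conditional normal); each missing cell takes the
  observed value of one of the **5** donors closest in predicted mean.
  Donor count 5 is the conventional PMM pool size; PMM guarantees
  imputations are plausible observed values and is robust to the
  skewed, bounded traits typical of germplasm descriptors.
* **Qualitative traits** — a draw from the predictive category
  distribution of a ridge-penalised multinomial logistic regression
  with penalty λ = 1/n. The shrinkage doubles as protection against
  separation and collinearity among descriptors.

Chains start from independent random fills drawn from each trait's
observed empirical distribution. Defaults: 4 chains × 30 iterations,
burn-in the first half, M = 30 completed datasets collected by
interleaving post-burn-in states across chains. Convergence is
monitored by the classic Gelman–Rubin potential scale reduction factor
√(V̂/W) on the per-trait mean and SD of the imputed cells (modal
frequency and its complement for qualitative traits), flagged at the
usual 1.1. Observed cells are never altered; a fully observed table
short-circuits to M identical copies.

One numerical caveat worth stating: with 4 chains the R̂ *estimate* has
appreciable Monte-Carlo error at short chain lengths. Simulating the
estimator at exact stationarity, the maximum over ~16 monitored
statistics exceeds 1.1 about 14% of the time with 15 retained draws per
chain, about 1% with 25, and essentially never with 40. Convergence-
asserting tests therefore run 80 iterations (40 retained draws); this
is a chain-length choice for the diagnostic, not a change to the 1.1
rule or to the sampler.

Pooling produces a completed *table* (not pooled model coefficients):
consensus pooling averages quantitative cells across the M tables and
takes the modal level for qualitative cells (ties broken by the higher
marginal frequency across all pooled tables, then by vocabulary order);
`first` returns completed table #1. Imputation quality is audited by
per-trait observed-vs-completed tests: pooled-variance t for
quantitative traits, chi-squared homogeneity (Yates for 2×2) for
qualitative ones.

## Weighted k-means on mixed data

Qualitative traits expand to one 0/1 indicator column per observed
level; quantitative columns are z-standardised by default (without
standardisation a trait measured in grams would swamp both the other
quantitative traits and the indicator block; a flag restores the
literal unstandardised objective). Column j carries weight w for
qualitative-derived columns and 1 − w for quantitative ones, w = 0.5 by
default so the two kinds contribute equally. Because
Σ_j w_j (x_j − c_j)² is the ordinary squared Euclidean distance after
scaling each column by √w_j, the weighted objective is minimised by
plain Lloyd alternation in the scaled coordinates, where the centroid
update is the cluster mean. Fits take the best of 25 k-means++
initialisations; an emptied cluster is reseeded to the point farthest
from its assigned centroid. On instances small enough to enumerate
(n ≤ 8, k ≤ 3) the fit equals the exhaustive partition optimum.

The cluster count is the smallest k whose occupancy proportions meet
all three criteria — normalised Shannon–Weaver ≥ 0.90, Nei ≥ 0.85,
variance explained (1 − P_k/P_1) ≥ 0.70. Note the Nei bound 1 − 1/S
makes the 0.85 threshold attainable only for k ≥ 7, so on data with few
well-separated groups no candidate passes all three; the selector then
returns the k maximising the minimum criterion margin and flags the
criteria as unmet. This is a real property of raw-threshold selection,
not a defect of the search. Per-trait (one-dimensional) clustering uses
the same machinery on a single standardised column and stores the
standardisation so core-collection members can be assigned to the
clusters fitted on the entire collection — keeping the two collections
comparable (refitting on the core is possible but changes the classes
being compared).

## Modified Roger's distance

For accessions i, i*: d² = d²_Eul + d²_mR with

* d²_Eul = Σ_{j∈C} (x_ij − x_i*j)² over quantitative traits (z-scored
  by default; `raw` evaluates the literal formula), and
* per qualitative trait, 0 when the two accessions share the level and
  (ln f_ij − ln f_i*j)² when they differ, where f is the level's
  relative frequency among observed cells of the whole collection.

Choices: natural logarithm (the log base only rescales the qualitative
term by a constant); frequencies computed once on the entire
collection, not per pair; traits with a missing cell in either
accession are skipped (pairwise-complete) with no rescaling by the
number of compared traits (an option normalises by it). Two inherent
properties are documented rather than corrected: different levels of
equal frequency contribute zero, exactly as matching levels do; and
while √d² is a pseudometric on complete cases, pairwise deletion can
violate the triangle inequality because different pairs may be compared
on different trait subsets.

## Core selection

"Maximal pairwise distance" is operationalised as maximin subset
selection, which is NP-hard exactly. The selector is deterministic:
farthest-point traversal (seed = globally farthest pair; ties by larger
distance sums, then id order; each step adds the accession with the
largest minimum distance to the selected set), restarted from the
farthest starting pairs (all pairs when n ≤ 40, the top 20 otherwise),
each candidate set then polished by a local exchange pass that swaps a
member for an outsider whenever it raises the (min, sum) pairwise-
distance pair lexicographically. A single greedy pass alone was
measured at a worst-case min-distance ratio of ≈ 0.67 against the
exhaustive optimum on 100 random 10-accession instances; with restarts
and exchange the selector attains the exact optimum on all of them.
The reported trace re-orders the final subset by farthest-point
insertion, so its criterion values are non-increasing after the seed
pair. Default core size is ⌈0.15 n⌉ (30 of 200). A greedy max-sum
variant and two classical comparators are included: simple random
sampling, and stratified proportional sampling with largest-remainder
quotas per cluster (remainder ties favour the smaller stratum, so
strata of 150/50 at k = 30 receive 22/8).

## Diversity and evaluation

Both diversity indices score class proportions p over the classes
present in the scored collection: H′ = −Σ p ln p / ln S (0 for S = 1 by
the defined limit) and Nei = 1 − Σ p². Classes are observed levels for
qualitative traits and per-trait cluster occupancy for quantitative
ones; S counts only non-empty classes, and proportions are over
non-missing observations in that collection.

Per-trait EC-vs-CC comparisons: a bootstrap Levene test (mean-centred W
statistic referred to B = 1,000 resamples of the pooled centred values
under the null, with the +1/(B+1) continuity term; an asymptotic-F
fallback exists) routes each quantitative trait to the pooled-variance
Student t (Levene p ≥ 0.05) or Welch t; qualitative traits use the
chi-squared test of homogeneity with Yates continuity correction iff
the table is 2×2 — that correction rule is what reproduces the
reference worked examples, and categories empty in both collections are
dropped first. α = 0.05 throughout with no multiplicity correction.

Aggregates over quantitative traits: MD% = (1/m)Σ|M_e−M_c|/M_c·100
(note the core mean in the denominator, implemented exactly as
defined), VD% analogously on variances, CR% = mean range ratio
R_c/R_e·100, VR% = mean CV ratio CV_c/CV_e·100. Coverage% = mean class
ratio D_c/D_e·100 over quantitative, qualitative and combined trait
sets separately. Zero-denominator traits are excluded from the affected
average with a warning. Verdict: representative iff at most 20% of
traits show a significant mean/distribution difference and CR% > 80%.

## Synthetic data: what it emulates, and what it does not

The generator mimics the structure of a curated vegetable-soybean-style
collection — defaults: 213 accessions, 15 quantitative + 14 qualitative
traits, 9 latent clusters, 13 byte-identical duplicate pairs, 15%
missing cells (the source collection's per-trait rates ranged from none
to mild, averaging about this), MCAR by default. Quantitative traits
draw per-cluster normals with equally spaced, randomly permuted cluster
centres `cluster_separation` within-SD units apart (default 3), on
deliberately disparate measurement scales; skew-flagged traits use a
mirrored log-normal (bulk high, a tail of extreme low values, as seen
in seed-weight-type descriptors). Each qualitative trait gives every
cluster a preferred level at probability ≈ 0.6 with Dirichlet-spread
remainder — informative but not deterministic. Duplicate pairs are
copied *after* masking so the pair shares its missingness pattern, as
real duplicated records do. MAR masking ties missingness to the
quartile of the first quantitative trait (weights 0.4/0.8/1.2/1.6 ×
rate, covariate never masked); rates above 0.30 are rejected as outside
the imputation method's validity range.

What passing tests on these data do **not** show: real descriptor
scales are ordinal with scoring conventions, traits are correlated
beyond cluster structure, missingness is often trait-block structured
(whole seasons unscored), and real redundancy can be near- rather than
exact duplication. Results on synthetic data certify the machinery, not
field performance.

## Problem sizes used in the test suite

Chosen for a single CPU: selector-optimality and cluster-recovery
checks use 100 seeded instances of 10 and 90 accessions respectively;
exhaustive clustering oracles use n ≤ 8, k ≤ 3; imputation calibration
uses four seeded 200-accession tables at 20% MCAR with 4 chains × 80
iterations; the bootstrap-Levene size check uses 1,000 repetitions at
B = 199 with the nominal ±0.02 band. The full suite runs in under two
minutes.
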