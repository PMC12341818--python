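# Methods

`cellclock` builds sample-level markers of biological aging from
multi-sample single-cell RNA-seq data. This note records the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic cohorts used by the test suite do
and do not establish about real data.

## Data model

A cohort is a set of N samples, each a non-negative cells × genes matrix
X_i ∈ R^{c_i × p} over one ordered gene vocabulary, with a donor id and a
continuous age y_i per sample. Ages carry an explicit unit tag (days,
months or gestational weeks) and are never converted automatically;
cross-cohort operations refuse to run until the caller reconciles units.
A donor may own several samples (repeated sample batches), and every
donor-level protocol keeps a donor's samples on one side of any split.
Gene identifiers are case-sensitive strings; no aliasing or ortholog
mapping is attempted. When an input container carries duplicate gene
symbols the first occurrence wins and a warning is logged. Cell and
sample order are preserved by every transformation so per-cell
annotations stay joinable by position.

## Preprocessing

The pipeline order is fixed: (1) per-sample downsampling to at most 750
cells, drawn uniformly without replacement (a compute-saving cap; samples
at or under the cap pass through unchanged); (2) counts-per-million
normalization — each cell with nonzero counts is rescaled to a total of
1e6 — followed by log(1 + x); all-zero cells pass through and are *not*
dropped; (3) selection of the 3000 most highly variable genes on the
pooled cells, by the dispersion-based (variance/mean, standardized within
mean bins) "seurat-flavor" ranking; cohorts measured on panels of ≤ 3000
genes are left unfiltered; zero-variance genes are never selected; (4)
PCA (top 40 components) on centered, unscaled log values of the pooled
cells; (5) a k-nearest-neighbor graph (k = 10, Euclidean distance in PC
space, exact neighbors, union-symmetrized edges); (6) Leiden clustering
with the RBConfiguration (modularity-with-resolution) quality at
resolution γ = 1. K, the number of clusters, is whatever the algorithm
finds; it varies with data size and heterogeneity. All stages are
deterministic given the master seed; per-sample and per-trial seeds are
derived through `numpy.random.SeedSequence` so any single step is
reproducible in isolation. HVG and PCA are computed on the pooled cells
(not per sample) because the clusters must define one common subtype
vocabulary across samples.

## Featurizations

Let cluster labels partition all pooled cells into K subtypes.

**Frequency** (d = K): entry m of sample i's vector is the fraction of
its cells assigned to cluster m; rows sum to 1 exactly.

**Classical pseudobulk over HVGs** (d = K · p_hvg): block m holds the
per-gene *sums* of expression over sample i's cells in cluster m; empty
(sample, cluster) pairs contribute zero blocks. Summing the blocks over
clusters reproduces the whole-sample aggregation used for bulk
extrapolation — an identity the tests assert exactly.

**Pseudobulk++** (d = K): a one-vs-rest differential-expression test is
run for every gene in every cluster on the pooled log-normalized cells.
The test is a Welch two-sample t statistic, with the large-sample t
treated as a z-score; any test producing a per-gene (z, p) pair can be
plugged in behind the same interface. Each gene keeps its most
significant cluster comparison; genes are ranked by p-value (ties broken
by larger |z|, then lexicographic gene id) and the top G (25 or 50 by
default) form one common weight vector f of absolute z-scores — a gene's
cluster of origin is deliberately not retained, and a gene reaching the
top in several clusters appears once with its maximal |z|. The feature
value for (sample i, cluster m) is the sum over the sample's cluster-m
cells of the inner product between the cell's expression on the G genes
and f: a frequency-scaled weighted expression score. Ranking pools the
best comparison per gene across clusters rather than taking a fixed
number per cluster; with tied numbers of significant genes per cluster
the two readings coincide, and the pooled form keeps the vector length
exactly G.

**Landmark kernel mean embedding** (d = L): L = 1500 landmark cells are
chosen across all samples by farthest-point (greedy k-center) sketching
from a seeded start (uniform random sampling is available as a fallback);
feature j of sample i is the mean RBF kernel value between the sample's
cells and landmark j, so features lie in (0, 1] and are invariant to cell
order. The bandwidth defaults to the median heuristic, γ_RBF = 1 / (2 ·
median pairwise squared distance among the landmarks). The embedding is
computed in the same 40-dimensional PC space used for clustering rather
than full gene space — distances there are denoised and metrically
stable — and the feature metadata records the space used.

Features are used raw (no per-column standardization) unless a model's
own configuration standardizes internally; either way is recorded.

## Age classification

Ages are binned by named rules with left-closed boundaries: a three-way
aging rule (young < 4, 4 ≤ adult < 14, old ≥ 14 months), a gestational
trimester rule (first 9–12, second 13–18 weeks, with 12 → first and
13 → second), an exact-timepoint rule for lifespan designs sampled at
fixed ages, and custom breakpoints. Classification runs 200 randomized
trials; each trial assigns 80% of *donors* (with all their samples) to
training, fits a random forest with 50 trees and sqrt-of-features
splits, and scores the fraction of held-out samples correctly labeled.
A donor-level variant (majority vote over a donor's samples; ties count
as incorrect) is reported alongside, since sample-level and donor-level
accuracy differ when donors contribute several samples. Trials whose
training split misses a class are re-drawn (logged, capped at 100
attempts per trial). Feature importance is the mean over trials of the
per-trial Gini (impurity-decrease) importances, each trial normalized to
sum to 1; a top-k extractor returns the most age-informative clusters
(k = 5 by default).

## Aging clocks

The clock is Lasso regression, objective (1/2N)·||y − Dβ||² + λ||β||₁,
evaluated by leave-one-donor-out cross-validation: one fold per donor,
the donor's samples held out together, λ tuned on each training fold by
5-fold internal cross-validation minimizing MSE over a 50-point
logarithmic grid spanning [1e-3, 1e1] times the fold's own path scale
(max |X_cᵀ y_c| / n, the smallest penalty that zeroes all coefficients).
Neither the grid span nor the internal fold count is protocol-critical;
both are recorded in the fitted model's penalty metadata. Donors with
several samples receive their mean predicted age. Quality is the Pearson
correlation r between chronological and predicted donor ages, with the
regression p-value of the fitted line. Features enter unstandardized by
default (a flag enables per-fold z-scoring).

**A caution on the LOOCV null.** When features carry no age signal, the
internally tuned Lasso usually selects the intercept-only model, whose
leave-one-donor-out prediction is the training-fold mean age
(S − a_d)/(n − 1) — an exact affine *decreasing* function of the held-out
age. The null distribution of r is therefore negatively biased (Monte
Carlo mean ≈ −0.5 at N = 40, reaching −1 exactly when every fold is
intercept-only), a known property of cross-validated correlation metrics.
A permutation test on this protocol must be read one-sided: absence of
signal shows up as r ≤ 0, and only the right tail is evidence of skill.
The analogous small-sample artifact exists for classification: on noise
features the held-out accuracy of ~20-sample designs sits *below* 1/2,
because the training majority class is depleted in the held-out set.

## Cross-dataset transfer

Two cohorts with a shared gene subset and reconciled age units are
intersected, downsampled and normalized identically. The reference is
clustered by the standard pipeline. Both cohorts are embedded jointly
after a pluggable batch correction — built-ins are `identity` (shared
PCA) and `standardize` (per-gene z-scoring within each cohort before the
shared PCA, which removes per-gene location/scale offsets exactly);
external integration algorithms can be passed as a callable and are not
re-implemented here. Each query cell receives the majority label among
its k = 10 nearest reference cells (ties broken by the nearest tied
neighbor). Frequency features over the reference label set are computed
for both cohorts — labels unobserved in the query contribute zero
columns — and an Elastic Net (l1_ratio 0.5, penalty tuned by 5-fold CV;
a fixed penalty is inappropriate for frequency features, whose scale is
bounded by 1) is trained on the reference samples only and evaluated on
the query by Pearson r. If a degenerate all-zero-coefficient model makes
predictions constant, r is reported as 0 (no association) rather than
left undefined.

## Single-cell → bulk extrapolation

Summing each gene over all of a sample's cells (across all clusters)
converts a cohort into a sample × gene matrix with bulk-like structure.
After restricting to the genes shared with the target bulk dataset, an
Elastic Net with fixed defaults α = 1 and l1_ratio = 0.5 is fitted with
an intercept. Prediction applies the intercept by default — a bare
linear score Bβ is scale-degenerate — but a flag exposes the
intercept-free form for comparison. Two screens operate on a
two-age-group bulk design: **key genes** keeps clock genes with
|β| ≥ 1.2 (inclusive) whose two-sided Welch t-test between age groups
reaches −log₁₀ p ≥ 5 (inclusive) in every condition present, reporting a
signed −log₁₀ p whose sign follows the coefficient; raising either
threshold can only shrink the list. **Stress screen** runs a two-sided
Wilcoxon rank-sum test of condition within each age group and
categorizes genes by which groups reach −log₁₀ p ≥ 2.5 (both, one group
only, or none). Logs use base 10, matching the magnitudes such screens
conventionally report; p-values are two-sided throughout.

## Synthetic cohorts

The generator draws, per donor, an age uniform over the cohort range (or
from a fixed timepoint list for lifespan designs), subtype proportions
softmax(log baseline + slope · (age − midpoint)), per-cell subtypes from
those proportions, and counts from a negative binomial with mean μ and
dispersion θ (var = μ + μ²/θ) — the standard overdispersed scRNA-seq
count model. Subtype identity multiplies marker-gene means by a fold
change; a designated gene set drifts monotonically with age on the
log-mean scale; per-gene baseline means vary log-normally. One sample
per donor is the default, with a batches-per-donor option for
donor-aggregation protocols and an optional per-sample library scale
factor. Defaults describe a continuously sampled mouse aging cohort: 40
donors aged 3–29 months, five subtypes at equal baseline with log-odds
slopes (±0.12, ±0.06, 0) per month, 1500 genes, 20 markers per subtype at
5-fold elevation, 100 age-drifting genes at ±0.02 per month, 100–400
cells per sample (typical post-downsampling depth for sorted microglia),
θ = 2. These sizes keep every end-to-end check — a 40-donor clock with a
50-permutation null, and a 30 + 30-donor cross-cohort transfer — well
under a desktop compute budget.

What the generator does **not** emulate: ambient RNA, doublets,
batch/chemistry effects beyond the optional scale factor, library-size
confounding with age, zero inflation beyond the NB, gene-gene
correlation within programs, and non-monotone expression trajectories.
Passing the recovery tests therefore shows the estimators are correct
and well-calibrated under the stated generative model — not that real
cohorts of this size will reach the same correlations.

## Numerical choices and degenerate inputs

Welch tests guard zero-variance groups (identical constants → z = 0,
p = 1; a zero standard error with unequal means is floored at 1e-300
before division). p-values are floored at 1e-300 before logs. Gene
ranking ties break deterministically (p, then −|z|, then gene id).
Landmark sketching starts from a seeded uniform draw. kNN graphs mask
self-edges explicitly so duplicate points cannot create them. All-zero
cells normalize to all-zero. Constant ages make correlation undefined
and raise; constant *predictions* (an all-zero clock) report r = 0.
Empty gene intersections, insufficient cells for k-NN or landmarks, and
out-of-domain ages raise informative errors rather than proceeding.

## Known limitations

* Clocks are linear (Lasso / Elastic Net); no nonlinear models.
* Batch correction ships only the two built-ins; integration methods
  such as mutual-nearest-neighbor algorithms must be plugged in.
* No QC beyond the stated pipeline: no doublet, ambient, mitochondrial
  or cell-cycle handling, and no gene-ID conversion.
* The LOOCV correlation metric's negative null bias (above) means
  absolute r values near zero from small cohorts should be interpreted
  against a permutation null, not against 0.
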