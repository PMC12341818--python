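# cellclock

Sample-level featurization of multi-donor single-cell RNA-seq data and
transcriptomic **aging clocks**.

Single-cell studies profile many cells per donor, but models of donor
age need one fixed-length vector per sample. `cellclock` implements four
unsupervised featurizations that compress a sample's cells × genes
matrix X_i ∈ R^{c_i × p} into a summary s_i ∈ R^d, and the protocols to
turn those summaries into markers of biological aging. It is aimed at
researchers working with cohorts of sorted cell populations — e.g.
microglia profiled across the lifespan — who want interpretable,
donor-level age classifiers and clocks that transfer across datasets and
extrapolate to bulk RNA-seq.

Given a common clustering of all cells into K subtypes:

* **frequency** — s_i ∈ R^K, the fraction of sample i's cells in each
  cluster (Σ_m s_im = 1);
* **pseudobulk (HVG)** — s_i ∈ R^{K·p_hvg}, per-cluster per-gene sums of
  expression over the highly variable genes;
* **pseudobulk++** — s_i ∈ R^K, one scalar per cluster,
  p̃_im = Σ_{cells c in cluster m} ⟨x_c[G genes], f⟩, where f holds the
  absolute z-scores of the top G one-vs-rest differentially expressed
  genes — a parsimonious blend of frequency and key-gene expression;
* **scLKME** — s_i ∈ R^L, the mean RBF-kernel similarity of the sample's
  cells to L landmark cells sketched from the pooled distribution,
  s_ij = (1/c_i) Σ_t κ(x_t, ℓ_j).

Downstream protocols: donor-level random-forest age-group classification
(200 randomized 80/20 donor splits, Gini feature importance), Lasso
aging clocks with leave-one-donor-out cross-validation
((1/2N)||y − Dβ||² + λ||β||₁, λ tuned per fold), kNN cluster-label
transfer between batch-corrected cohorts, and single-cell → bulk Elastic
Net extrapolation (α = 1, l1_ratio = 0.5) with key-gene and
stress-responsive gene screens. A seeded synthetic-cohort generator
(negative-binomial counts, age-drifting subtype proportions and gene
programs) makes the whole stack testable without any data download.

## Worked example

```python
import numpy as np
from cellclock.simulate import SimulationConfig, simulate_cohort
from cellclock.preprocess import PreprocessConfig, run_pipeline
from cellclock.featurize import frequency_features
from cellclock.clocks import (AgeBinningRule, bin_ages, classify_age_groups,
                              gini_importance, lasso_clock_loocv)

cfg = SimulationConfig(n_donors=20, seed=3)          # 3-29 month cohort
ds, true_labels, _ = simulate_cohort(cfg)
res = run_pipeline(ds, PreprocessConfig(seed=0))     # cap 750 / CPM / HVG / PCA / kNN / Leiden
ft = frequency_features(res.dataset, res.clusters)

groups = bin_ages(ds.ages, AgeBinningRule.three_way_aging())
report = classify_age_groups(ft, groups, np.array(ds.donor_ids), seed=0)
gini = gini_importance(ft, groups, np.array(ds.donor_ids), n_trials=50, seed=0)
clock, _ = lasso_clock_loocv(ft, ds.ages, np.array(ds.donor_ids), seed=0)
```

Output:

```
cohort: 20 donors, 4554 cells, 1500 genes (months)
Leiden found K = 5 clusters
frequency features: 20 samples x 5 features
age-group accuracy: 0.958 +/- 0.103 over 200 trials
top age-predictive clusters: ['cluster1', 'cluster3', 'cluster0']
LOOCV clock: Pearson r = 0.992 (p = 1.80e-17)
```

The clustering recovers the five simulated subtypes; their frequencies
alone classify young/adult/old donors with 96% mean accuracy and, as a
continuous clock, predict held-out donors' ages with r = 0.99. The Gini
ranking names the clusters whose abundance drifts with age — the
interpretable output a practitioner would follow up on.

A `cellclock` command-line tool exposes the same steps as subcommands
(`simulate-cohort`, `preprocess`, `featurize`, `classify`, `clock`,
`transfer-clock`, `sc2bulk`, `keygenes`); run `cellclock --help`.

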