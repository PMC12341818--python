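"""Sample-level featurizations of a clustered single-cell cohort.

Four strategies turn each sample's cells x genes matrix into one fixed-
length vector:

* **frequency** — the proportion of the sample's cells in each of the K
  shared clusters (d = K).
* **pbhvg** — classical pseudobulk: per-cluster per-gene sums of
  expression, concatenated over clusters (d = K * p).
* **pbpp** — a per-cluster scalar combining cell frequency with weighted
  expression of the top differentially expressed genes; the weights are
  absolute z-scores from one-vs-rest tests (d = K).
* **sclkme** — landmark kernel mean embedding: the mean RBF kernel value
  between the sample's cells and each of L landmark cells chosen by
  sketching the pooled distribution (d = L).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.metrics.pairwise import rbf_kernel

from .core import ClusterAssignment, FeatureTable, MultiSampleDataset

__all__ = [
    "GeneWeightVector",
    "LandmarkSet",
    "frequency_features",
    "pbhvg_features",
    "pbpp_gene_weights",
    "pbpp_features",
    "select_landmarks",
    "sclkme_features",
]


@dataclass
class GeneWeightVector:
    """Top differentially expressed genes with |z|-score weights.

    ``weights[q]`` is the absolute z-score of gene ``gene_ids[q]`` in its
    most significant one-vs-rest cluster comparison; ``pvalues`` carries
    the corresponding p-values for transparency.
    """

    gene_ids: list[str]
    weights: np.ndarray
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.gene_ids) != self.weights.shape[0]:
            raise ValueError("gene_ids and weights must have equal length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if (self.weights < 0).any():
            raise ValueError("weights are absolute z-scores and must be >= 0")

    @property
    def G(self) -> int:
        return len(self.gene_ids)


@dataclass
class LandmarkSet:
    """L landmark cells (rows of ``coords``) with an RBF bandwidth.

    ``gamma`` is the coefficient in ``exp(-gamma * ||x - l||^2)``. When not
    given it is set by the median heuristic over the landmarks:
    ``1 / (2 * median pairwise squared distance)``.
    """

    coords: np.ndarray
    cell_indices: np.ndarray
    gamma: float | None = None
    feature_space: str = "unspecified"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_indices = np.asarray(self.cell_indices, dtype=int)
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one landmark")
        if self.gamma is None:
            self.gamma = median_heuristic_gamma(self.coords)

    @property
    def L(self) -> int:
        return self.coords.shape[0]


def median_heuristic_gamma(coords: np.ndarray) -> float:
    """RBF bandwidth 1 / (2 * median pairwise squared distance)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(coords, metric="sqeuclidean")))
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med)


# ---------------------------------------------------------------------------
# frequency
# ---------------------------------------------------------------------------

def frequency_features(ds: MultiSampleDataset, clusters: ClusterAssignment) -> FeatureTable:
    """Per-sample cluster proportions (rows sum to 1)."""
    per_sample = clusters.per_sample(ds)
    matrix = np.zeros((ds.N, clusters.K))
    for i, lab in enumerate(per_sample):
        counts = np.bincount(lab, minlength=clusters.K)
        matrix[i] = counts / lab.shape[0]
    names = [f"cluster{m}" for m in range(clusters.K)]
    return FeatureTable(
        matrix=matrix, feature_names=names, method="frequency", sample_ids=ds.sample_ids,
        meta={"K": clusters.K},
    )


# ---------------------------------------------------------------------------
# classical pseudobulk over HVGs
# ---------------------------------------------------------------------------

def pbhvg_features(ds: MultiSampleDataset, clusters: ClusterAssignment) -> FeatureTable:
    """Per-cluster per-gene expression sums, concatenated over clusters.

    Block ``m`` of row ``i`` holds, for every gene, the sum of its
    expression over sample ``i``'s cells assigned to cluster ``m``;
    (sample, cluster) pairs with no cells contribute all-zero blocks. The
    caller is expected to have restricted the dataset to highly variable
    genes first (d = K * p_hvg).
    """
    per_sample = clusters.per_sample(ds)
    K, p = clusters.K, ds.p
    matrix = np.zeros((ds.N, K * p))
    for i, (s, lab) in enumerate(zip(ds.samples, per_sample)):
        for m in range(K):
            mask = lab == m
            if mask.any():
                matrix[i, m * p : (m + 1) * p] = s.matrix[mask].sum(axis=0)
    names = [f"cluster{m}|{g}" for m in range(K) for g in ds.gene_ids]
    return FeatureTable(
        matrix=matrix, feature_names=names, method="pbhvg", sample_ids=ds.sample_ids,
        meta={"K": K, "p_hvg": p},
    )


# ---------------------------------------------------------------------------
# Pseudobulk++
# ---------------------------------------------------------------------------

def _welch_one_vs_rest(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene Welch t statistic and two-sided p, cluster vs rest."""
    a, b = X[mask], X[~mask]
    n1, n0 = a.shape[0], b.shape[0]
    m1, m0 = a.mean(axis=0), b.mean(axis=0)
    v1, v0 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = v1 / n1 + v0 / n0
    t = (m1 - m0) / np.sqrt(np.maximum(se2, 1e-300))
    # Welch-Satterthwaite degrees of freedom; guard the zero-variance case
    num = se2**2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
    df = np.divide(num, den, out=np.full_like(num, n1 + n0 - 2.0), where=den > 0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # identical constant groups: no evidence either way
    both_const = (se2 == 0) & (m1 == m0)
    t = np.where(both_const, 0.0, t)
    p = np.where(both_const, 1.0, p)
    return t, p


def pbpp_gene_weights(
    ds: MultiSampleDataset, clusters: ClusterAssignment, G: int = 50
) -> GeneWeightVector:
    """Top-G differentially expressed genes across one-vs-rest cluster tests.

    For every gene, a Welch two-sample t statistic (treated as a z-score)
    is computed for each cluster against the rest on the pooled log-
    normalized cells; the gene keeps its most significant comparison.
    Genes are ranked from most to least significant p-value, with
    deterministic tie-breaks (larger |z|, then lexicographic gene id), and
    the top G are returned with weights = |z|. A gene's cluster of origin
    is not retained: the G genes form one common weight vector.
    """
    if G > ds.p:
        raise ValueError(f"G={G} exceeds the vocabulary size p={ds.p}")
    if clusters.K < 2:
        raise ValueError("need at least two clusters for one-vs-rest tests")
    X = ds.pooled_matrix()
    labels = clusters.labels
    best_p = np.ones(ds.p)
    best_absz = np.zeros(ds.p)
    for m in range(clusters.K):
        mask = labels == m
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        t, p = _welch_one_vs_rest(X, mask)
        absz = np.abs(t)
        better = (p < best_p) | ((p == best_p) & (absz > best_absz))
        best_p = np.where(better, p, best_p)
        best_absz = np.where(better, absz, best_absz)
    order = sorted(range(ds.p), key=lambda q: (best_p[q], -best_absz[q], ds.gene_ids[q]))
    top = order[:G]
    return GeneWeightVector(
        gene_ids=[ds.gene_ids[q] for q in top],
        weights=best_absz[top],
        pvalues=best_p[top],
    )


def pbpp_features(
    ds: MultiSampleDataset, clusters: ClusterAssignment, w: GeneWeightVector
) -> FeatureTable:
    """One scalar per (sample, cluster): summed weighted key-gene expression.

    Entry (i, m) is the sum, over sample i's cells in cluster m, of the
    inner product between the cell's expression on the G key genes and the
    weight vector — a frequency-scaled weighted expression score. Empty
    (sample, cluster) pairs give 0.
    """
    gindex = {g: q for q, g in enumerate(ds.gene_ids)}
    missing = [g for g in w.gene_ids if g not in gindex]
    if missing:
        raise ValueError(f"weight genes not in dataset vocabulary: {missing[:5]}")
    cols = np.array([gindex[g] for g in w.gene_ids], dtype=int)
    per_sample = clusters.per_sample(ds)
    matrix = np.zeros((ds.N, clusters.K))
    for i, (s, lab) in enumerate(zip(ds.samples, per_sample)):
        scores = s.matrix[:, cols] @ w.weights  # per-cell weighted expression
        matrix[i] = np.bincount(lab, weights=scores, minlength=clusters.K)
    names = [f"cluster{m}" for m in range(clusters.K)]
    return FeatureTable(
        matrix=matrix, feature_names=names, method="pbpp", sample_ids=ds.sample_ids,
        meta={"K": clusters.K, "G": w.G},
    )


# ---------------------------------------------------------------------------
# landmark kernel mean embedding
# ---------------------------------------------------------------------------

def select_landmarks(
    data: MultiSampleDataset | np.ndarray,
    L: int = 1500,
    seed: int = 0,
    method: str = "kcenter",
    gamma: float | None = None,
    feature_space: str = "unspecified",
) -> LandmarkSet:
    """Choose L landmark cells covering the pooled cell distribution.

    ``method='kcenter'`` (default) uses farthest-point (greedy k-center)
    sketching from a seeded random start; ``method='random'`` samples
    uniformly without replacement. ``data`` may be a dataset (its pooled
    matrix is used) or an explicit cells x features array such as PC
    coordinates.
    """
    X = data.pooled_matrix() if isinstance(data, MultiSampleDataset) else np.asarray(data, dtype=float)
    n = X.shape[0]
    if L < 1:
        raise ValueError("L must be >= 1")
    if n < L:
        raise ValueError(
            f"pooled cell count {n} is smaller than L={L}; lower L to at most {n}"
        )
    rng = np.random.default_rng(seed)
    if method == "random":
        idx = np.sort(rng.choice(n, size=L, replace=False))
    elif method == "kcenter":
        chosen = np.empty(L, dtype=int)
        chosen[0] = int(rng.integers(n))
        dist = np.sum((X - X[chosen[0]]) ** 2, axis=1)
        for j in range(1, L):
            chosen[j] = int(np.argmax(dist))
            d_new = np.sum((X - X[chosen[j]]) ** 2, axis=1)
            np.minimum(dist, d_new, out=dist)
        idx = chosen
    else:
        raise ValueError(f"unknown sketching method {method!r}")
    return LandmarkSet(coords=X[idx], cell_indices=idx, gamma=gamma, feature_space=feature_space)


def sclkme_features(ds: MultiSampleDataset, lm: LandmarkSet) -> FeatureTable:
    """Mean RBF kernel value between each sample's cells and each landmark.

    Entry (i, j) = mean over sample i's cells of
    ``exp(-gamma * ||cell - landmark_j||^2)``; values lie in (0, 1]. The
    dataset must live in the same feature space as the landmarks (e.g.
    both in PC coordinates).
    """
    if ds.p != lm.coords.shape[1]:
        raise ValueError(
            f"dataset has {ds.p} features but landmarks have {lm.coords.shape[1]}; "
            "featurize in the space the landmarks were selected in"
        )
    matrix = np.zeros((ds.N, lm.L))
    for i, s in enumerate(ds.samples):
        K = rbf_kernel(s.matrix, lm.coords, gamma=lm.gamma)
        matrix[i] = K.mean(axis=0)
    names = [f"landmark{j}" for j in range(lm.L)]
    return FeatureTable(
        matrix=matrix, feature_names=names, method="sclkme", sample_ids=ds.sample_ids,
        meta={"L": lm.L, "gamma": lm.gamma, "feature_space": lm.feature_space},
    )
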