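"""Cross-dataset evaluation and single-cell to bulk extrapolation.

Two cohorts profiled separately can share an aging clock if their cluster
labels are reconciled: reference labels are transferred to query cells by
k-nearest-neighbor voting in a jointly embedded space (after a pluggable
batch correction), and frequency features over the shared label set feed
an Elastic Net model trained on the reference only.

A single-cell cohort also extrapolates to bulk RNA-seq: summing each
gene's expression over all of a sample's cells yields a sample x gene
matrix with the same structure as bulk data, on which an Elastic Net age
model (alpha = 1, l1_ratio = 0.5) is trained and then applied to real bulk
profiles restricted to the shared gene vocabulary. Screens over the
resulting model identify key age genes (coefficient and significance
filters) and stress-responsive genes (per-age-group rank-sum tests).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.neighbors import NearestNeighbors

from .clocks import ClockModel, EvalReport
from .core import ClusterAssignment, FeatureTable, MultiSampleDataset, intersect_genes
from .featurize import frequency_features
from .preprocess import (
    PreprocessConfig,
    downsample_dataset,
    embed_and_graph,
    leiden_cluster,
    normalize_dataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMap",
    "BulkMatrix",
    "BatchCorrection",
    "CrossDatasetResult",
    "correct_batches",
    "map_cluster_labels",
    "cross_dataset_clock",
    "sc_to_bulk_matrix",
    "fit_bulk_en_clock",
    "predict_bulk_ages",
    "select_key_genes",
    "stress_gene_screen",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LabelMap:
    """Reference cluster labels transferred onto query cells."""

    reference_id: str
    query_id: str
    labels: np.ndarray  # one reference cluster label per query cell
    k: int


@dataclass
class BulkMatrix:
    """A bulk sample x gene expression matrix with design metadata."""

    matrix: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    age_group: np.ndarray | None = None
    condition: np.ndarray | None = None
    ages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("matrix shape must be n_samples x n_genes")

    def column(self, gene: str) -> np.ndarray:
        return self.matrix[:, self.gene_ids.index(gene)]


@dataclass
class BatchCorrection:
    """Joint embedding of two cohorts after a pluggable correction.

    ``ref_corrected`` / ``query_corrected`` are pooled cells x genes
    matrices in the corrected gene space; embeddings are rows of a PCA
    fitted on both cohorts' corrected cells together.
    """

    method: str
    gene_ids: list[str]
    ref_corrected: np.ndarray
    query_corrected: np.ndarray
    ref_embedding: np.ndarray
    query_embedding: np.ndarray


# ---------------------------------------------------------------------------
# batch correction and label mapping
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def correct_batches(
    ref_ds: MultiSampleDataset,
    query_ds: MultiSampleDataset,
    method: str = "standardize",
    n_pcs: int = 40,
    seed: int = 0,
) -> BatchCorrection:
    """Align two cohorts into one low-dimensional embedding.

    Built-in methods: ``"identity"`` (shared PCA on the raw pooled
    matrices) and ``"standardize"`` (per-gene z-scoring within each cohort
    before the shared PCA, which removes per-gene location/scale offsets
    between cohorts). External integration algorithms can be plugged in by
    passing a callable ``method(ref_matrix, query_matrix) -> (ref, query)``
    operating on pooled cells x genes matrices.
    """
    ref_r, shared = intersect_genes(ref_ds, query_ds.gene_ids)
    query_r, _ = intersect_genes(query_ds, shared)
    # align query columns to the reference's shared-gene order
    order = [query_r.gene_ids.index(g) for g in shared]
    Xq = query_r.pooled_matrix()[:, order]
    Xr = ref_r.pooled_matrix()

    if callable(method):
        Xr_c, Xq_c = method(Xr, Xq)
        method_name = getattr(method, "__name__", "custom")
    elif method == "identity":
        Xr_c, Xq_c = Xr, Xq
        method_name = "identity"
    elif method == "standardize":
        Xr_c, Xq_c = _standardize(Xr), _standardize(Xq)
        method_name = "standardize"
    else:
        raise ValueError(f"unknown batch-correction method {method!r}")

    n_comp = min(n_pcs, Xr_c.shape[0] + Xq_c.shape[0] - 1, len(shared))
    pca = PCA(n_components=n_comp, svd_solver="covariance_eigh", random_state=seed)
    joint = pca.fit_transform(np.vstack([Xr_c, Xq_c]))
    return BatchCorrection(
        method=method_name,
        gene_ids=shared,
        ref_corrected=Xr_c,
        query_corrected=Xq_c,
        ref_embedding=joint[: Xr_c.shape[0]],
        query_embedding=joint[Xr_c.shape[0] :],
    )


def map_cluster_labels(
    ref_embedding: np.ndarray,
    ref_labels: np.ndarray,
    query_embedding: np.ndarray,
    k: int = 10,
    reference_id: str = "reference",
    query_id: str = "query",
) -> LabelMap:
    """Majority vote among each query cell's k nearest reference cells.

    Ties are broken by the label of the nearest reference cell among the
    tied classes.
    """
    ref_embedding = np.asarray(ref_embedding, dtype=float)
    ref_labels = np.asarray(ref_labels, dtype=int)
    query_embedding = np.asarray(query_embedding, dtype=float)
    if k > ref_embedding.shape[0]:
        raise ValueError(f"k={k} exceeds the reference size {ref_embedding.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(ref_embedding)
    _, idx = nn.kneighbors(query_embedding)  # neighbors ordered by distance
    out = np.empty(query_embedding.shape[0], dtype=int)
    K = int(ref_labels.max()) + 1
    for i, neighbors in enumerate(idx):
        votes = ref_labels[neighbors]
        counts = np.bincount(votes, minlength=K)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            # nearest neighbor whose label is among the tied classes
            tied_set = set(tied.tolist())
            out[i] = next(v for v in votes if v in tied_set)
    return LabelMap(reference_id=reference_id, query_id=query_id, labels=out, k=k)


@dataclass
class CrossDatasetResult:
    report: EvalReport
    label_map: LabelMap
    model: ClockModel
    ref_features: FeatureTable
    query_features: FeatureTable
    ref_clusters: ClusterAssignment


def cross_dataset_clock(
    ref_ds: MultiSampleDataset,
    query_ds: MultiSampleDataset,
    k: int = 10,
    seed: int = 0,
    correction: str = "standardize",
    cfg: PreprocessConfig | None = None,
    ref_clusters: ClusterAssignment | None = None,
    l1_ratio: float = 0.5,
) -> CrossDatasetResult:
    """Train an age clock on one cohort and evaluate it on another.

    Both cohorts (raw counts, with reconciled age units) are restricted to
    their shared genes, downsampled and CPM/log normalized. The reference
    is clustered (unless labels are supplied), its labels are transferred
    to query cells by kNN voting in a batch-corrected joint embedding, and
    frequency features over the reference label set are computed for both
    cohorts. An Elastic Net (penalty tuned by cross-validation at the
    given ``l1_ratio``) is fitted on the reference samples only; the
    report carries query predictions and the Pearson correlation with
    chronological age.
    """
    if ref_ds.age_unit != query_ds.age_unit:
        raise ValueError(
            f"age units differ ({ref_ds.age_unit!r} vs {query_ds.age_unit!r}); "
            "reconcile them before cross-dataset modeling"
        )
    cfg = cfg or PreprocessConfig()
    ref_r, shared = intersect_genes(ref_ds, query_ds.gene_ids)
    query_r, _ = intersect_genes(query_ds, shared)

    ref_p, _ = downsample_dataset(ref_r, cap=cfg.cell_cap, seed=cfg.seed)
    query_p, _ = downsample_dataset(query_r, cap=cfg.cell_cap, seed=cfg.seed)
    ref_n = normalize_dataset(ref_p, target=cfg.cpm_target)
    query_n = normalize_dataset(query_p, target=cfg.cpm_target)

    if ref_clusters is None:
        pcs, graph = embed_and_graph(ref_n, n_pcs=cfg.n_pcs, k=cfg.knn_k, seed=cfg.seed)
        ref_clusters = leiden_cluster(graph, resolution=cfg.leiden_resolution, seed=cfg.seed)

    corr = correct_batches(ref_n, query_n, method=correction, n_pcs=cfg.n_pcs, seed=seed)
    label_map = map_cluster_labels(
        corr.ref_embedding, ref_clusters.labels, corr.query_embedding, k=k
    )
    query_clusters = ClusterAssignment(
        labels=label_map.labels, K=ref_clusters.K, resolution=ref_clusters.resolution
    )
    ref_ft = frequency_features(ref_n, ref_clusters)
    query_ft = frequency_features(query_n, query_clusters)

    en = ElasticNetCV(l1_ratio=l1_ratio, cv=5, max_iter=50_000, random_state=seed)
    en.fit(ref_ft.matrix, ref_n.ages)
    model = ClockModel(
        coefficients=en.coef_,
        intercept=float(en.intercept_),
        feature_names=list(ref_ft.feature_names),
        penalty={"model": "elastic_net_cv", "alpha": float(en.alpha_), "l1_ratio": l1_ratio},
        age_unit=ref_ds.age_unit,
    )
    pred = model.predict(query_ft.matrix)
    true = query_n.ages
    if np.std(pred) == 0:
        # an all-zero-coefficient clock predicts one constant age: there is
        # no association to measure
        logger.info("clock predictions are constant; reporting r=0")
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(true, pred)
    predictions = pd.DataFrame(
        {"donor_id": query_n.donor_ids, "age": true, "predicted_age": pred}
    )
    report = EvalReport(
        task="regression", predictions=predictions, pearson_r=float(r), p_value=float(p)
    )
    return CrossDatasetResult(
        report=report,
        label_map=label_map,
        model=model,
        ref_features=ref_ft,
        query_features=query_ft,
        ref_clusters=ref_clusters,
    )


# ---------------------------------------------------------------------------
# single-cell -> bulk extrapolation
# ---------------------------------------------------------------------------

def sc_to_bulk_matrix(ds: MultiSampleDataset) -> np.ndarray:
    """Aggregate each gene over all of a sample's cells (sum), per sample.

    Produces an ``N x p`` matrix with the same structure as bulk RNA-seq
    data: entry (i, q) is the summed expression of gene q across every
    cell of sample i, regardless of cluster.
    """
    return np.vstack([s.matrix.sum(axis=0) for s in ds.samples])


def fit_bulk_en_clock(
    X: np.ndarray,
    ages: np.ndarray,
    gene_ids: list[str],
    alpha: float = 1.0,
    l1_ratio: float = 0.5,
    age_unit: str = "unspecified",
) -> ClockModel:
    """Elastic Net age model on aggregated (bulk-like) expression.

    Uses the fixed default penalties alpha = 1 and l1_ratio = 0.5 and fits
    an intercept.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(gene_ids):
        raise ValueError("X columns must match gene_ids")
    en = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=50_000)
    en.fit(X, np.asarray(ages, dtype=float))
    return ClockModel(
        coefficients=en.coef_,
        intercept=float(en.intercept_),
        feature_names=list(gene_ids),
        penalty={"model": "elastic_net", "alpha": alpha, "l1_ratio": l1_ratio},
        age_unit=age_unit,
    )


def predict_bulk_ages(
    model: ClockModel, bulk: BulkMatrix, include_intercept: bool = True
) -> np.ndarray:
    """Apply a fitted clock to bulk samples over the shared vocabulary.

    The bulk gene vocabulary must match the model's training vocabulary
    (any order); use :func:`cellclock.core.intersect_genes` beforehand if
    it does not. The intercept is applied by default; ``include_intercept=
    False`` gives the bare linear score B @ beta.
    """
    if list(bulk.gene_ids) != list(model.feature_names):
        if set(bulk.gene_ids) != set(model.feature_names):
            raise ValueError(
                "bulk gene vocabulary does not match the clock's training vocabulary; "
                "restrict both to their intersection first (see intersect_genes)"
            )
        order = [bulk.gene_ids.index(g) for g in model.feature_names]
        X = bulk.matrix[:, order]
    else:
        X = bulk.matrix
    return model.predict(X, include_intercept=include_intercept)


# ---------------------------------------------------------------------------
# gene screens on bulk designs
# ---------------------------------------------------------------------------

def _neglog10(p: float) -> float:
    return float(-np.log10(max(p, 1e-300)))


def _two_age_groups(bulk: BulkMatrix) -> tuple[str, str]:
    if bulk.age_group is None:
        raise ValueError("bulk matrix has no age_group metadata")
    groups = list(pd.unique(bulk.age_group))
    if len(groups) != 2:
        raise ValueError(f"need exactly two age groups, found {groups}")
    return groups[0], groups[1]


def select_key_genes(
    model: ClockModel,
    bulk: BulkMatrix,
    coef_min: float = 1.2,
    neglogp_min: float = 5.0,
) -> pd.DataFrame:
    """Age-relevant clock genes that replicate in a two-age-group bulk design.

    A gene is retained when its clock coefficient has absolute value
    >= ``coef_min`` (inclusive) AND its two-sided t-test between the two
    age groups reaches -log10 p >= ``neglogp_min`` (inclusive) in *every*
    condition present. The returned frame carries the coefficient and, per
    condition, a signed -log10 p whose sign is the sign of the
    coefficient (the display convention for key-gene bar plots). Raising
    either threshold can only shrink the gene list.
    """
    g_young, g_old = _two_age_groups(bulk)
    conditions = (
        list(pd.unique(bulk.condition)) if bulk.condition is not None else ["all"]
    )
    rows = []
    for gene, coef in zip(model.feature_names, model.coefficients):
        if abs(coef) < coef_min or gene not in bulk.gene_ids:
            continue
        x = bulk.column(gene)
        entry = {"gene": gene, "coefficient": float(coef)}
        passed = True
        for cond in conditions:
            mask = np.ones(len(bulk.sample_ids), dtype=bool) if cond == "all" else (
                bulk.condition == cond
            )
            a = x[mask & (bulk.age_group == g_young)]
            b = x[mask & (bulk.age_group == g_old)]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(
                    f"age group with < 2 samples in condition {cond!r}"
                )
            _, p = stats.ttest_ind(a, b, equal_var=False)
            nl = _neglog10(float(p))
            entry[f"signed_neglogp_{cond}"] = float(np.sign(coef) * nl)
            if nl < neglogp_min:
                passed = False
        if passed:
            rows.append(entry)
    columns = ["gene", "coefficient"] + [f"signed_neglogp_{c}" for c in conditions]
    return pd.DataFrame(rows, columns=columns)


def stress_gene_screen(
    bulk: BulkMatrix,
    genes: list[str] | None = None,
    neglogp_min: float = 2.5,
) -> pd.DataFrame:
    """Classify genes by which age group shows a condition effect.

    Within each age group, a two-sided Wilcoxon rank-sum test compares the
    two conditions for each gene. Genes are categorized by the set of age
    groups reaching -log10 p >= ``neglogp_min``: both groups, one group
    only (``"<group>-only"``), or ``"none"``.
    """
    if bulk.condition is None:
        raise ValueError("bulk matrix has no condition metadata")
    g_a, g_b = _two_age_groups(bulk)
    conds = list(pd.unique(bulk.condition))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, found {conds}")
    genes = list(genes) if genes is not None else list(bulk.gene_ids)
    rows = []
    for gene in genes:
        x = bulk.column(gene)
        entry: dict = {"gene": gene}
        passing = []
        for grp in (g_a, g_b):
            in_grp = bulk.age_group == grp
            a = x[in_grp & (bulk.condition == conds[0])]
            b = x[in_grp & (bulk.condition == conds[1])]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"condition group with < 2 samples at age {grp!r}")
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            nl = _neglog10(float(p))
            entry[f"neglogp_{grp}"] = nl
            if nl >= neglogp_min:
                passing.append(grp)
        if len(passing) == 2:
            entry["category"] = "both"
        elif len(passing) == 1:
            entry["category"] = f"{passing[0]}-only"
        else:
            entry["category"] = "none"
        rows.append(entry)
    return pd.DataFrame(rows, columns=["gene", f"neglogp_{g_a}", f"neglogp_{g_b}", "category"])
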