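"""Per-sample and pooled preprocessing for multi-sample cohorts.

The pipeline order is fixed: per-sample cell downsampling, counts-per-
million normalization with log(1+x), highly-variable-gene selection on the
pooled cells, PCA, k-nearest-neighbor graph, Leiden clustering. Clustering
is performed on all cells pooled across samples so that cluster labels
define one common set of cell subtypes for the whole cohort.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core import CellSample, ClusterAssignment, MultiSampleDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "downsample_cells",
    "downsample_dataset",
    "cpm_log_normalize",
    "normalize_dataset",
    "select_hvg",
    "embed_and_graph",
    "leiden_cluster",
    "run_pipeline",
    "PipelineResult",
]


@dataclass
class PreprocessConfig:
    """Tunable knobs of the preprocessing pipeline.

    Defaults are the protocol constants used throughout: at most 750 cells
    kept per sample, CPM target sum 1e6, 3000 highly variable genes, 40
    principal components, 10 nearest neighbors, Leiden resolution 1.0.
    """

    cell_cap: int = 750
    cpm_target: float = 1e6
    n_hvg: int = 3000
    n_pcs: int = 40
    knn_k: int = 10
    leiden_resolution: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("cell_cap", "cpm_target", "n_hvg", "n_pcs", "knn_k", "leiden_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not isinstance(self.cell_cap, int):
            raise ValueError("cell_cap must be an integer")


# ---------------------------------------------------------------------------
# per-sample stages
# ---------------------------------------------------------------------------

def downsample_cells(
    sample: CellSample, cap: int = 750, seed: int = 0, return_index: bool = False
):
    """Keep at most ``cap`` cells, chosen uniformly without replacement.

    If the sample has ``cap`` cells or fewer it is returned unchanged
    (same membership). The retained cells keep their original relative
    order, so per-cell annotations can be subset with the same index.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if sample.n_cells <= cap:
        idx = np.arange(sample.n_cells)
        out = sample
    else:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(sample.n_cells, size=cap, replace=False))
        out = CellSample(
            matrix=sample.matrix[idx],
            sample_id=sample.sample_id,
            donor_id=sample.donor_id,
            age=sample.age,
        )
    return (out, idx) if return_index else out


def downsample_dataset(
    ds: MultiSampleDataset, cap: int = 750, seed: int = 0
) -> tuple[MultiSampleDataset, list[np.ndarray]]:
    """Apply the per-sample cell cap to a whole cohort.

    Per-sample seeds are derived from the master seed so each sample's
    draw is independent and reproducible.
    """
    samples, indices = [], []
    for i, s in enumerate(ds.samples):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        out, idx = downsample_cells(s, cap=cap, seed=child, return_index=True)
        samples.append(out)
        indices.append(idx)
    return MultiSampleDataset(samples=samples, gene_ids=list(ds.gene_ids), age_unit=ds.age_unit), indices


def cpm_log_normalize(sample: CellSample, target: float = 1e6) -> CellSample:
    """Counts-per-million followed by log(1+x), per cell.

    Each cell with nonzero total counts is rescaled so its counts sum to
    ``target``; all-zero cells pass through as zeros. Every entry is then
    replaced by ``log(1 + x)``.
    """
    totals = sample.matrix.sum(axis=1, keepdims=True)
    scale = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
    matrix = np.log1p(sample.matrix * scale)
    return CellSample(
        matrix=matrix, sample_id=sample.sample_id, donor_id=sample.donor_id, age=sample.age
    )


def normalize_dataset(ds: MultiSampleDataset, target: float = 1e6) -> MultiSampleDataset:
    return ds.with_matrices([cpm_log_normalize(s, target).matrix for s in ds.samples])


# ---------------------------------------------------------------------------
# pooled stages
# ---------------------------------------------------------------------------

def select_hvg(ds: MultiSampleDataset, n: int = 3000) -> tuple[MultiSampleDataset, list[str]]:
    """Restrict a (log-normalized) cohort to the ``n`` most variable genes.

    Uses the standard dispersion-based ranking (variance/mean, standardized
    within mean bins — scanpy's ``seurat`` flavor) computed on the pooled
    cells. When the vocabulary already has ``n`` genes or fewer the dataset
    is returned unchanged, mirroring cohorts measured on small panels where
    no additional filtering is applied.
    """
    if ds.p <= n:
        return ds, list(ds.gene_ids)
    import anndata as ad
    import pandas as pd
    import scanpy as sc

    adata = ad.AnnData(
        X=ds.pooled_matrix(), var=pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id"))
    )
    sc.pp.highly_variable_genes(adata, n_top_genes=n, flavor="seurat")
    score = adata.var["dispersions_norm"].to_numpy(dtype=float)
    score = np.where(np.isfinite(score), score, -np.inf)
    # a gene with no variance carries no information regardless of its
    # binned dispersion score
    score[adata.X.var(axis=0) == 0] = -np.inf
    # exact top-n with a deterministic tie-break on vocabulary position
    order = np.lexsort((np.arange(ds.p), -score))
    keep = np.sort(order[:n])
    sub = ds.subset_genes(keep)
    return sub, list(sub.gene_ids)


def embed_and_graph(
    ds: MultiSampleDataset, n_pcs: int = 40, k: int = 10, seed: int = 0
) -> tuple[np.ndarray, sparse.csr_matrix]:
    """PCA on the pooled cells and a symmetrized k-nearest-neighbor graph.

    PCA is computed on centered (not scaled) values; neighbors use
    Euclidean distance in PC space. The adjacency is the union of directed
    kNN edges, so every cell has at least ``k`` neighbors.
    """
    X = ds.pooled_matrix()
    n_cells = X.shape[0]
    if n_cells <= n_pcs:
        raise ValueError(f"need more than n_pcs={n_pcs} pooled cells, got {n_cells}")
    if n_cells < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells for a {k}-NN graph")
    n_comp = min(n_pcs, n_cells - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="covariance_eigh", random_state=seed)
    pcs = pca.fit_transform(X)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    rows = np.repeat(np.arange(n_cells), k)
    # drop the self column; in degenerate duplicate-point cases the self may
    # not be first, so mask it explicitly
    neigh = []
    for i in range(n_cells):
        cand = [j for j in idx[i] if j != i][:k]
        while len(cand) < k:  # all-duplicate corner case
            cand.append(i)
        neigh.append(cand)
    cols = np.asarray(neigh).ravel()
    adj = sparse.csr_matrix(
        (np.ones_like(rows, dtype=float), (rows, cols)), shape=(n_cells, n_cells)
    )
    adj = adj.maximum(adj.T)
    return pcs, adj


def leiden_cluster(
    graph: sparse.spmatrix, resolution: float = 1.0, seed: int = 0
) -> ClusterAssignment:
    """Leiden community detection on a cell-cell graph.

    Uses the RBConfiguration (modularity with resolution) quality function.
    The number of clusters K is determined by the algorithm and depends on
    the data and the resolution.
    """
    import igraph as ig
    import leidenalg

    adj = sparse.csr_matrix(graph)
    n = adj.shape[0]
    coo = sparse.triu(adj, k=1).tocoo()
    g = ig.Graph(n=n, edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership, dtype=int)
    return ClusterAssignment(labels=labels, K=int(labels.max()) + 1 if n else 1, resolution=resolution)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the fixed preprocessing pipeline produces."""

    dataset: MultiSampleDataset  # downsampled, normalized, HVG-restricted
    hvg_genes: list[str]
    pcs: np.ndarray
    graph: sparse.csr_matrix
    clusters: ClusterAssignment
    kept_cell_indices: list[np.ndarray] = field(default_factory=list)


def run_pipeline(ds: MultiSampleDataset, cfg: PreprocessConfig | None = None) -> PipelineResult:
    """Run the full fixed-order pipeline on a raw-count cohort."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    logger.info("stage 1/6: downsample (cap=%d)", cfg.cell_cap)
    ds_ds, kept = downsample_dataset(ds, cap=cfg.cell_cap, seed=cfg.seed)
    logger.info("stage 2/6: CPM + log1p (target=%g)", cfg.cpm_target)
    ds_norm = normalize_dataset(ds_ds, target=cfg.cpm_target)
    logger.info("stage 3/6: HVG selection (n=%d)", cfg.n_hvg)
    ds_hvg, hvg = select_hvg(ds_norm, n=cfg.n_hvg)
    logger.info("stage 4/6: PCA (n_pcs=%d); stage 5/6: kNN graph (k=%d)", cfg.n_pcs, cfg.knn_k)
    pcs, graph = embed_and_graph(ds_hvg, n_pcs=cfg.n_pcs, k=cfg.knn_k, seed=cfg.seed)
    logger.info("stage 6/6: Leiden clustering (resolution=%g)", cfg.leiden_resolution)
    clusters = leiden_cluster(graph, resolution=cfg.leiden_resolution, seed=cfg.seed)
    counts = np.bincount(clusters.labels, minlength=clusters.K)
    logger.info("found K=%d clusters; per-cluster cell counts: %s", clusters.K, counts.tolist())
    return PipelineResult(
        dataset=ds_hvg,
        hvg_genes=hvg,
        pcs=pcs,
        graph=graph,
        clusters=clusters,
        kept_cell_indices=kept,
    )
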