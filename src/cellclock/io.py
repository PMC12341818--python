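"""Readers and writers for cohort data.

Supported on-disk forms:

* AnnData ``.h5ad`` containers holding all cells pooled, with per-cell
  ``obs`` columns ``sample_id``, ``donor_id`` and ``age`` and the gene
  vocabulary in ``var`` (age unit in ``uns``).
* Per-sample Matrix Market triplets (``matrix.mtx`` genes x cells,
  ``genes.tsv``, ``barcodes.tsv``) and dense CSV (cells x genes).
* A sample metadata table: CSV with columns
  ``sample_id, donor_id, age, age_unit``.

Duplicate gene symbols are resolved by keeping the first occurrence; a
warning is logged when this happens.
"""
from __future__ import annotations

import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core import CellSample, MultiSampleDataset

logger = logging.getLogger(__name__)

__all__ = [
    "to_anndata",
    "from_anndata",
    "write_h5ad",
    "read_h5ad",
    "write_sample_mtx",
    "read_sample_mtx",
    "write_sample_csv",
    "read_sample_csv",
    "write_metadata_csv",
    "read_metadata_csv",
]


def _dedupe_genes(gene_ids: list[str]) -> np.ndarray:
    """Indices keeping the first occurrence of each gene symbol."""
    seen: set[str] = set()
    keep = []
    for i, g in enumerate(gene_ids):
        if g not in seen:
            seen.add(g)
            keep.append(i)
    if len(keep) != len(gene_ids):
        logger.warning(
            "dropped %d duplicate gene symbols (first occurrence wins)",
            len(gene_ids) - len(keep),
        )
    return np.array(keep, dtype=int)


def to_anndata(ds: MultiSampleDataset) -> ad.AnnData:
    """Pool a cohort into one AnnData with per-cell sample metadata."""
    X = ds.pooled_matrix()
    obs = pd.DataFrame(
        {
            "sample_id": np.repeat(ds.sample_ids, ds.n_cells),
            "donor_id": np.repeat(ds.donor_ids, ds.n_cells),
            "age": np.repeat(ds.ages, ds.n_cells),
        }
    )
    obs.index = [f"{sid}:cell{i}" for sid, n in zip(ds.sample_ids, ds.n_cells) for i in range(n)]
    var = pd.DataFrame(index=pd.Index(ds.gene_ids, name="gene_id"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["age_unit"] = ds.age_unit
    return adata


def from_anndata(adata: ad.AnnData) -> MultiSampleDataset:
    """Rebuild a cohort from a pooled AnnData (inverse of :func:`to_anndata`).

    Samples are returned in order of first appearance in ``obs.sample_id``;
    cell order within each sample is preserved.
    """
    gene_ids = [str(g) for g in adata.var_names]
    keep = _dedupe_genes(gene_ids)
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)[:, keep]
    gene_ids = [gene_ids[i] for i in keep]

    obs = adata.obs
    sample_order = obs["sample_id"].astype(str)
    samples = []
    for sid in pd.unique(sample_order):
        mask = (sample_order == sid).to_numpy()
        sub = obs[mask]
        samples.append(
            CellSample(
                matrix=X[mask],
                sample_id=str(sid),
                donor_id=str(sub["donor_id"].iloc[0]),
                age=float(sub["age"].iloc[0]),
            )
        )
    age_unit = str(adata.uns.get("age_unit", "unknown"))
    return MultiSampleDataset(samples=samples, gene_ids=gene_ids, age_unit=age_unit)


def write_h5ad(ds: MultiSampleDataset, path: str | Path) -> None:
    to_anndata(ds).write_h5ad(Path(path))


def read_h5ad(path: str | Path) -> MultiSampleDataset:
    return from_anndata(ad.read_h5ad(Path(path)))


# ---------------------------------------------------------------------------
# per-sample matrix formats
# ---------------------------------------------------------------------------

def write_sample_mtx(sample: CellSample, gene_ids: list[str], directory: str | Path) -> None:
    """Write one sample as an MTX triplet (genes x cells, like cellranger)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.csr_matrix(sample.matrix.T))
    pd.Series(gene_ids).to_csv(directory / "genes.tsv", sep="\t", index=False, header=False)
    barcodes = [f"{sample.sample_id}:cell{i}" for i in range(sample.n_cells)]
    pd.Series(barcodes).to_csv(directory / "barcodes.tsv", sep="\t", index=False, header=False)


def read_sample_mtx(
    directory: str | Path, sample_id: str, donor_id: str, age: float
) -> tuple[CellSample, list[str]]:
    directory = Path(directory)
    mat = spio.mmread(directory / "matrix.mtx")
    matrix = np.asarray(sparse.csr_matrix(mat).toarray(), dtype=float).T
    gene_ids = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    sample = CellSample(matrix=matrix, sample_id=sample_id, donor_id=donor_id, age=age)
    return sample, gene_ids


def write_sample_csv(sample: CellSample, gene_ids: list[str], path: str | Path) -> None:
    index = [f"{sample.sample_id}:cell{i}" for i in range(sample.n_cells)]
    pd.DataFrame(sample.matrix, index=index, columns=gene_ids).to_csv(Path(path))


def read_sample_csv(
    path: str | Path, sample_id: str, donor_id: str, age: float
) -> tuple[CellSample, list[str]]:
    df = pd.read_csv(Path(path), index_col=0)
    sample = CellSample(
        matrix=df.to_numpy(dtype=float), sample_id=sample_id, donor_id=donor_id, age=age
    )
    return sample, [str(c) for c in df.columns]


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def write_metadata_csv(ds: MultiSampleDataset, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "donor_id": ds.donor_ids,
            "age": ds.ages,
            "age_unit": ds.age_unit,
        }
    ).to_csv(Path(path), index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    required = {"sample_id", "donor_id", "age", "age_unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df
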