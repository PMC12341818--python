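"""Shared data model for multi-sample single-cell expression cohorts.

A cohort is a collection of per-sample cells x genes matrices sharing one
ordered gene vocabulary, together with per-sample donor identifiers and
ages. Ages are continuous and carry an explicit unit tag (days, months or
gestational weeks); nothing in this package ever converts between units —
cross-cohort operations require the caller to reconcile them first.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CellSample",
    "MultiSampleDataset",
    "ClusterAssignment",
    "FeatureTable",
    "validate_dataset",
    "intersect_genes",
    "embedding_dataset",
]


@dataclass
class CellSample:
    """A single profiled sample: one cells x genes matrix plus metadata.

    Parameters
    ----------
    matrix
        Non-negative expression values with one row per cell (raw counts
        or normalized values; shape ``(c_i, p)``).
    sample_id
        Unique identifier of the sample within its cohort.
    donor_id
        Identifier of the donor the sample came from. One donor may own
        several samples (e.g. repeated sample batches).
    age
        Donor age at sampling, in the cohort's declared unit.
    """

    matrix: np.ndarray
    sample_id: str
    donor_id: str
    age: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(
                f"sample {self.sample_id!r}: matrix must be 2-D, got ndim={self.matrix.ndim}"
            )

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MultiSampleDataset:
    """An ordered collection of :class:`CellSample` over one gene vocabulary."""

    samples: list[CellSample]
    gene_ids: list[str]
    age_unit: str = "months"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)

    # -- basic shape accessors -------------------------------------------------
    @property
    def N(self) -> int:
        """Number of samples."""
        return len(self.samples)

    @property
    def p(self) -> int:
        """Size of the gene vocabulary."""
        return len(self.gene_ids)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.samples], dtype=float)

    @property
    def donor_ids(self) -> list[str]:
        return [s.donor_id for s in self.samples]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_cells(self) -> np.ndarray:
        return np.array([s.n_cells for s in self.samples], dtype=int)

    @property
    def total_cells(self) -> int:
        return int(self.n_cells.sum())

    # -- pooled views ----------------------------------------------------------
    def pooled_matrix(self) -> np.ndarray:
        """All cells stacked in sample order (``total_cells x p``)."""
        return np.vstack([s.matrix for s in self.samples])

    def cell_sample_index(self) -> np.ndarray:
        """For each pooled cell, the index of the sample it belongs to."""
        return np.repeat(np.arange(self.N), self.n_cells)

    def split_pooled(self, values: np.ndarray) -> list[np.ndarray]:
        """Split a pooled per-cell array back into per-sample arrays."""
        values = np.asarray(values)
        if values.shape[0] != self.total_cells:
            raise ValueError(
                f"pooled array has {values.shape[0]} rows, dataset has {self.total_cells} cells"
            )
        bounds = np.cumsum(self.n_cells)[:-1]
        return np.split(values, bounds)

    # -- transformations -------------------------------------------------------
    def with_matrices(
        self, matrices: Sequence[np.ndarray], gene_ids: Sequence[str] | None = None
    ) -> "MultiSampleDataset":
        """Return a copy whose samples carry new matrices (metadata preserved)."""
        if len(matrices) != self.N:
            raise ValueError("need one matrix per sample")
        genes = list(gene_ids) if gene_ids is not None else list(self.gene_ids)
        samples = [replace(s, matrix=np.asarray(m, dtype=float)) for s, m in zip(self.samples, matrices)]
        return MultiSampleDataset(samples=samples, gene_ids=genes, age_unit=self.age_unit)

    def subset_genes(self, indices: np.ndarray) -> "MultiSampleDataset":
        indices = np.asarray(indices, dtype=int)
        genes = [self.gene_ids[i] for i in indices]
        return self.with_matrices([s.matrix[:, indices] for s in self.samples], genes)


@dataclass
class ClusterAssignment:
    """Per-cell subtype labels over ``K`` clusters, in pooled cell order."""

    labels: np.ndarray
    K: int
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.K):
            raise ValueError("labels must lie in [0, K)")

    def per_sample(self, ds: MultiSampleDataset) -> list[np.ndarray]:
        return ds.split_pooled(self.labels)


@dataclass
class FeatureTable:
    """An ``N x d`` sample-level feature matrix produced by a featurization."""

    matrix: np.ndarray
    feature_names: list[str]
    method: str
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.feature_names)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_dataset(ds: MultiSampleDataset) -> list[str]:
    """Check every invariant of the data model; never raises.

    Returns an empty list iff the dataset is well formed, otherwise one
    human-readable record per violation naming the offending sample and rule.
    """
    violations: list[str] = []
    if ds.N == 0:
        violations.append("dataset: contains no samples")
    if ds.p == 0:
        violations.append("dataset: empty gene vocabulary")
    if len(set(ds.gene_ids)) != len(ds.gene_ids):
        violations.append("dataset: duplicate gene identifiers in vocabulary")
    seen_ids: set[str] = set()
    for s in ds.samples:
        sid = s.sample_id
        if sid in seen_ids:
            violations.append(f"sample {sid!r}: duplicate sample_id")
        seen_ids.add(sid)
        if s.matrix.shape[1] != ds.p:
            violations.append(
                f"sample {sid!r}: gene vocabulary mismatch "
                f"({s.matrix.shape[1]} columns, vocabulary has {ds.p})"
            )
        if s.n_cells < 1:
            violations.append(f"sample {sid!r}: contains no cells (c_i >= 1 required)")
        if s.matrix.size and not np.isfinite(s.matrix).all():
            violations.append(f"sample {sid!r}: non-finite expression values")
        elif s.matrix.size and (s.matrix < 0).any():
            violations.append(f"sample {sid!r}: negative expression values")
        if not np.isfinite(s.age) or s.age < 0:
            violations.append(f"sample {sid!r}: age must be finite and non-negative")
        if not s.donor_id:
            violations.append(f"sample {sid!r}: missing donor_id")
    return violations


# ---------------------------------------------------------------------------
# gene-vocabulary handling
# ---------------------------------------------------------------------------

def intersect_genes(
    ds: MultiSampleDataset, other_vocab: Iterable[str]
) -> tuple[MultiSampleDataset, list[str]]:
    """Restrict a dataset to genes shared with another vocabulary.

    The output vocabulary is the ordered intersection, with column order
    following ``ds`` (first argument). Expression values of retained genes
    are unchanged. Gene identifiers are case-sensitive; no aliasing or
    ortholog mapping is attempted.

    Raises
    ------
    ValueError
        If the vocabularies share no genes.
    """
    other = set(other_vocab)
    if not other:
        raise ValueError("other vocabulary is empty")
    indices = np.array([i for i, g in enumerate(ds.gene_ids) if g in other], dtype=int)
    if indices.size == 0:
        raise ValueError("incompatible gene vocabularies: empty intersection")
    shared = [ds.gene_ids[i] for i in indices]
    if len(shared) == ds.p:
        return ds, shared
    return ds.subset_genes(indices), shared


def embedding_dataset(ds: MultiSampleDataset, coords: np.ndarray, prefix: str = "PC") -> MultiSampleDataset:
    """Re-express a dataset's cells in an embedding (e.g. principal components).

    ``coords`` holds one row per pooled cell, in dataset order. The returned
    dataset carries the embedding columns as its "genes" (``PC1``, ``PC2``,
    ...), so featurizations that operate on cell coordinates (such as the
    landmark kernel mean embedding) can reuse the same data model.
    """
    coords = np.asarray(coords, dtype=float)
    parts = ds.split_pooled(coords)
    names = [f"{prefix}{j + 1}" for j in range(coords.shape[1])]
    return ds.with_matrices(parts, names)
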