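"""Shared fixtures: small synthetic cohorts generated at test time."""
from __future__ import annotations

import numpy as np
import pytest

from cellclock.core import CellSample, MultiSampleDataset, validate_dataset
from cellclock.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A fast 12-donor cohort with three subtypes and clear age trends."""
    return SimulationConfig(
        n_donors=12,
        K_true=3,
        frequency_slopes=(0.15, -0.15, 0.0),
        n_genes=300,
        markers_per_subtype=10,
        marker_fold_change=6.0,
        n_age_modulated_genes=20,
        cells_per_sample=(60, 100),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    ds, labels, props = simulate_cohort(small_cfg)
    assert validate_dataset(ds) == []
    return ds, labels, props


@pytest.fixture()
def tiny_dataset() -> MultiSampleDataset:
    """Three hand-built samples over a 4-gene vocabulary."""
    genes = ["A", "B", "C", "D"]
    samples = [
        CellSample(np.array([[1.0, 2, 0, 1], [3, 4, 1, 0]]), "s0", "d0", 2.0),
        CellSample(np.array([[0.0, 1, 1, 1]]), "s1", "d1", 5.0),
        CellSample(np.array([[2.0, 0, 0, 3], [1, 1, 1, 1], [0, 0, 0, 0]]), "s2", "d2", 9.0),
    ]
    return MultiSampleDataset(samples=samples, gene_ids=genes, age_unit="months")
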