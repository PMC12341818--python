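"""Batch correction, label transfer, bulk extrapolation and gene screens."""
from __future__ import annotations

import numpy as np
import pytest

from cellclock.clocks import ClockModel
from cellclock.core import CellSample, ClusterAssignment, MultiSampleDataset
from cellclock.featurize import frequency_features
from cellclock.simulate import SimulationConfig, simulate_cohort, simulate_stress_bulk
from cellclock.transfer import (
    BulkMatrix,
    correct_batches,
    cross_dataset_clock,
    fit_bulk_en_clock,
    map_cluster_labels,
    predict_bulk_ages,
    sc_to_bulk_matrix,
    select_key_genes,
    stress_gene_screen,
)


def _dataset(matrices, genes, ages=None, unit="months"):
    ages = ages or [1.0] * len(matrices)
    samples = [
        CellSample(np.asarray(m, dtype=float), f"s{i}", f"d{i}", a)
        for i, (m, a) in enumerate(zip(matrices, ages))
    ]
    return MultiSampleDataset(samples=samples, gene_ids=list(genes), age_unit=unit)


class TestCorrectBatches:
    def test_identity_method_on_identical_datasets(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, size=(30, 8)).astype(float)
        ds = _dataset([X], [f"g{i}" for i in range(8)])
        corr = correct_batches(ds, ds, method="identity", n_pcs=4)
        np.testing.assert_allclose(corr.ref_embedding, corr.query_embedding, atol=1e-9)

    def test_standardization_removes_constant_per_gene_offset(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5.0, 1.0, size=(40, 6))
        offset = np.arange(6, dtype=float) * 3.0
        ds_ref = _dataset([X], [f"g{i}" for i in range(6)])
        ds_qry = _dataset([X + offset], [f"g{i}" for i in range(6)])
        corr = correct_batches(ds_ref, ds_qry, method="standardize", n_pcs=4)
        gap = corr.ref_corrected.mean(axis=0) - corr.query_corrected.mean(axis=0)
        assert np.abs(gap).max() < 1e-9

    def test_unknown_method_raises(self, tiny_dataset):
        with pytest.raises(ValueError, match="method"):
            correct_batches(tiny_dataset, tiny_dataset, method="scano")

    def test_disjoint_vocabularies_raise(self):
        a = _dataset([np.ones((3, 2))], ["a", "b"])
        b = _dataset([np.ones((3, 2))], ["c", "d"])
        with pytest.raises(ValueError):
            correct_batches(a, b)

    def test_standardization_improves_label_transfer_under_scaling(self):
        """A per-sample library-size factor distorts raw distances; per-gene
        z-scoring should recover at least as good transfer, paired over seeds."""
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_donors=6, K_true=3, frequency_slopes=(0.0, 0.0, 0.0), n_genes=120,
                markers_per_subtype=12, marker_fold_change=8.0, n_age_modulated_genes=0,
                cells_per_sample=(80, 120), seed=100 + seed,
            )
            ref, ref_lab, _ = simulate_cohort(cfg)
            cfg_q = SimulationConfig(**{**cfg.__dict__, "seed": 200 + seed,
                                        "sample_scale_range": (0.3, 3.0)})
            qry, qry_lab, _ = simulate_cohort(cfg_q)
            accs = {}
            for method in ("identity", "standardize"):
                corr = correct_batches(ref, qry, method=method, n_pcs=10)
                lm = map_cluster_labels(
                    corr.ref_embedding, np.concatenate(ref_lab), corr.query_embedding, k=10
                )
                accs[method] = np.mean(lm.labels == np.concatenate(qry_lab))
            wins += accs["standardize"] >= accs["identity"]
        assert wins >= 7


class TestMapClusterLabels:
    def test_identical_points_with_k1_copy_labels(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(20, 3))
        labels = rng.integers(0, 4, size=20)
        lm = map_cluster_labels(ref, labels, ref, k=1)
        np.testing.assert_array_equal(lm.labels, labels)

    def test_point_near_centroid_gets_that_cluster(self):
        ref = np.vstack([np.zeros((10, 2)), np.full((10, 2), 10.0)])
        labels = np.repeat([0, 1], 10)
        query = np.array([[0.1, -0.1], [9.8, 10.1]])
        lm = map_cluster_labels(ref, labels, query, k=5)
        np.testing.assert_array_equal(lm.labels, [0, 1])

    def test_k_larger_than_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            map_cluster_labels(np.zeros((3, 2)), np.zeros(3, dtype=int), np.zeros((1, 2)), k=5)

    def test_transfer_recovers_shared_subtypes(self):
        cfg = SimulationConfig(
            n_donors=8, K_true=3, frequency_slopes=(0.1, -0.1, 0.0), n_genes=150,
            markers_per_subtype=15, marker_fold_change=8.0, n_age_modulated_genes=0,
            cells_per_sample=(100, 150), seed=31,
        )
        ref, ref_lab, _ = simulate_cohort(cfg)
        qry, qry_lab, _ = simulate_cohort(
            SimulationConfig(**{**cfg.__dict__, "seed": 32})
        )
        corr = correct_batches(ref, qry, method="standardize", n_pcs=10)
        lm = map_cluster_labels(
            corr.ref_embedding, np.concatenate(ref_lab), corr.query_embedding, k=10
        )
        agreement = np.mean(lm.labels == np.concatenate(qry_lab))
        assert agreement >= 0.9


class TestCrossDatasetClock:
    def test_self_transfer_on_strong_signal_is_nearly_perfect(self):
        cfg = SimulationConfig(n_donors=16, n_genes=400, cells_per_sample=(80, 150), seed=41)
        ds, _, _ = simulate_cohort(cfg)
        res = cross_dataset_clock(ds, ds, k=10, seed=0)
        assert res.report.pearson_r >= 0.95

    def test_age_signal_free_pair_shows_no_association(self):
        base = dict(
            n_donors=12, K_true=3, frequency_slopes=(0.0, 0.0, 0.0), n_genes=150,
            markers_per_subtype=10, n_age_modulated_genes=0, cells_per_sample=(60, 100),
        )
        ref, _, _ = simulate_cohort(SimulationConfig(**base, seed=51))
        qry, _, _ = simulate_cohort(SimulationConfig(**base, seed=52))
        res = cross_dataset_clock(ref, qry, k=10, seed=0)
        assert abs(res.report.pearson_r) < 0.6  # inside the 12-donor null band

    def test_mismatched_age_units_raise(self):
        a = _dataset([np.ones((30, 3))], ["a", "b", "c"], unit="months")
        b = _dataset([np.ones((30, 3))], ["a", "b", "c"], unit="weeks")
        with pytest.raises(ValueError, match="unit"):
            cross_dataset_clock(a, b)


class TestScToBulk:
    def test_column_sum_oracle(self):
        ds = _dataset([np.array([[1.0, 2.0], [3.0, 4.0]])], ["a", "b"])
        np.testing.assert_array_equal(sc_to_bulk_matrix(ds), [[4.0, 6.0]])

    def test_single_cell_sample_is_its_own_bulk_row(self):
        ds = _dataset([np.array([[5.0, 7.0, 0.0]])], ["a", "b", "c"])
        np.testing.assert_array_equal(sc_to_bulk_matrix(ds), [[5.0, 7.0, 0.0]])

    def test_equals_pbhvg_blocks_summed_over_clusters(self, small_cohort):
        from cellclock.featurize import pbhvg_features

        ds, labels, _ = small_cohort
        ca = ClusterAssignment(labels=np.concatenate(labels), K=3)
        ft = pbhvg_features(ds, ca)
        per_gene = ft.matrix.reshape(ds.N, ca.K, ds.p).sum(axis=1)
        np.testing.assert_allclose(per_gene, sc_to_bulk_matrix(ds), atol=1e-9)


class TestBulkClock:
    def test_self_prediction_matches_fitted_values(self, small_cohort):
        ds, _, _ = small_cohort
        X = sc_to_bulk_matrix(ds)
        model = fit_bulk_en_clock(X, ds.ages, ds.gene_ids)
        assert model.penalty == {"model": "elastic_net", "alpha": 1.0, "l1_ratio": 0.5}
        bulk = BulkMatrix(matrix=X, sample_ids=ds.sample_ids, gene_ids=ds.gene_ids)
        pred = predict_bulk_ages(model, bulk)
        np.testing.assert_allclose(pred, model.predict(X), atol=1e-8)

    def test_all_zero_coefficients_predict_the_intercept(self):
        model = ClockModel(
            coefficients=np.zeros(3), intercept=7.5, feature_names=["a", "b", "c"],
            penalty={"model": "elastic_net", "alpha": 1.0, "l1_ratio": 0.5},
        )
        bulk = BulkMatrix(
            matrix=np.random.default_rng(0).normal(size=(5, 3)),
            sample_ids=[f"s{i}" for i in range(5)], gene_ids=["a", "b", "c"],
        )
        np.testing.assert_allclose(predict_bulk_ages(model, bulk), 7.5)
        np.testing.assert_allclose(
            predict_bulk_ages(model, bulk, include_intercept=False), 0.0
        )

    def test_vocabulary_mismatch_raises_with_intersection_advice(self):
        model = ClockModel(
            coefficients=np.ones(2), intercept=0.0, feature_names=["a", "b"],
            penalty={},
        )
        bulk = BulkMatrix(matrix=np.ones((4, 2)), sample_ids=list("wxyz"), gene_ids=["a", "c"])
        with pytest.raises(ValueError, match="intersect"):
            predict_bulk_ages(model, bulk)

    def test_reordered_vocabulary_is_aligned_not_rejected(self):
        model = ClockModel(
            coefficients=np.array([1.0, 10.0]), intercept=0.0, feature_names=["a", "b"],
            penalty={},
        )
        bulk = BulkMatrix(
            matrix=np.array([[2.0, 3.0]]), sample_ids=["s"], gene_ids=["b", "a"]
        )
        np.testing.assert_allclose(predict_bulk_ages(model, bulk), [3.0 + 20.0])

    def test_zero_noise_synthetic_bulk_separates_age_groups(self):
        """Mirrors a two-age-group bulk validation: a clock trained on
        aggregated single-cell counts must separate young from old bulk
        samples built from the same generative process."""
        from scipy import stats as sps

        base = dict(
            n_donors=20, K_true=3, frequency_slopes=(0.2, -0.2, 0.0), n_genes=200,
            markers_per_subtype=15, n_age_modulated_genes=40,
            age_modulation_slope=0.05, cells_per_sample=(80, 120),
            age_range=(1.0, 10.0),
        )
        train, _, _ = simulate_cohort(SimulationConfig(**base, seed=61))
        model = fit_bulk_en_clock(sc_to_bulk_matrix(train), train.ages, train.gene_ids)
        young, _, _ = simulate_cohort(
            SimulationConfig(**{**base, "n_donors": 10, "age_range": (1.0, 2.0), "seed": 62})
        )
        old, _, _ = simulate_cohort(
            SimulationConfig(**{**base, "n_donors": 10, "age_range": (9.0, 10.0), "seed": 63})
        )
        pred = {}
        for name, ds in (("young", young), ("old", old)):
            bulk = BulkMatrix(
                matrix=sc_to_bulk_matrix(ds), sample_ids=ds.sample_ids, gene_ids=ds.gene_ids
            )
            pred[name] = predict_bulk_ages(model, bulk)
        t, p = sps.ttest_ind(pred["young"], pred["old"])
        assert p < 0.01 and pred["old"].mean() > pred["young"].mean()


def _screen_fixture(seed=0):
    genes = [f"g{i}" for i in range(30)]
    X, sids, grp, cond = simulate_stress_bulk(
        genes,
        n_per_group=6,
        age_effect_genes={"g0": 8.0, "g1": 8.0, "g2": 0.0},
        stress_effect_genes={"g3": {"P200": 3.0}, "g4": {"P9": 3.0, "P200": 3.0}},
        noise_sd=1.0,
        seed=seed,
    )
    return BulkMatrix(matrix=X, sample_ids=sids, gene_ids=genes, age_group=grp, condition=cond)


class TestSelectKeyGenes:
    def _model(self, coefs):
        genes = [f"g{i}" for i in range(30)]
        c = np.zeros(30)
        for g, v in coefs.items():
            c[genes.index(g)] = v
        return ClockModel(coefficients=c, intercept=0.0, feature_names=genes, penalty={})

    def test_strong_gene_above_both_thresholds_is_retained_with_sign(self):
        bulk = _screen_fixture()
        model = self._model({"g0": 1.3, "g1": -2.0, "g2": 1.5})
        df = select_key_genes(model, bulk, coef_min=1.2, neglogp_min=5.0)
        assert set(df["gene"]) == {"g0", "g1"}  # g2 has no age effect
        row = df[df["gene"] == "g1"].iloc[0]
        assert row["signed_neglogp_CTR"] < 0  # sign follows the coefficient

    def test_zero_coefficient_excluded_regardless_of_p(self):
        bulk = _screen_fixture()
        model = self._model({"g0": 0.0})
        assert select_key_genes(model, bulk).empty

    def test_boundary_thresholds_are_inclusive(self):
        bulk = _screen_fixture()
        model = self._model({"g0": 1.2})
        df0 = select_key_genes(model, bulk, coef_min=1.2, neglogp_min=0.0)
        assert list(df0["gene"]) == ["g0"]
        df1 = select_key_genes(model, bulk, coef_min=1.2000001, neglogp_min=0.0)
        assert df1.empty

    def test_monotone_in_both_thresholds(self):
        bulk = _screen_fixture()
        model = self._model({"g0": 1.3, "g1": -2.0, "g3": 1.25})
        base = set(select_key_genes(model, bulk, coef_min=1.2, neglogp_min=2.0)["gene"])
        higher_coef = set(select_key_genes(model, bulk, coef_min=1.28, neglogp_min=2.0)["gene"])
        higher_p = set(select_key_genes(model, bulk, coef_min=1.2, neglogp_min=8.0)["gene"])
        assert higher_coef <= base and higher_p <= base

    def test_tiny_group_raises(self):
        bulk = _screen_fixture()
        keep = np.arange(len(bulk.sample_ids)) != 0  # break one design cell
        small = BulkMatrix(
            matrix=bulk.matrix[keep][:13], sample_ids=bulk.sample_ids[:13],
            gene_ids=bulk.gene_ids, age_group=bulk.age_group[keep][:13],
            condition=bulk.condition[keep][:13],
        )
        # construct a degenerate design with a singleton cell
        small.age_group[:] = "P9"
        small.age_group[0] = "P200"
        model = self._model({"g0": 2.0})
        with pytest.raises(ValueError, match="< 2 samples"):
            select_key_genes(model, small)


class TestStressScreen:
    def test_old_only_effect_is_categorized(self):
        bulk = _screen_fixture(seed=3)
        df = stress_gene_screen(bulk, genes=["g3", "g4"], neglogp_min=2.0)
        assert df.set_index("gene").loc["g3", "category"] == "P200-only"
        assert df.set_index("gene").loc["g4", "category"] == "both"

    def test_null_genes_rarely_pass(self):
        bulk = _screen_fixture(seed=4)
        null_genes = [f"g{i}" for i in range(10, 30)]
        df = stress_gene_screen(bulk, genes=null_genes, neglogp_min=2.5)
        assert (df["category"] == "none").mean() >= 0.9

    def test_threshold_zero_passes_everything_as_both(self):
        bulk = _screen_fixture()
        df = stress_gene_screen(bulk, neglogp_min=0.0)
        assert (df["category"] == "both").all()
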