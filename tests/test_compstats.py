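"""Single-nucleus QC, composition ANOVA, the kNN/KL statistic and DEG
overlap arithmetic."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from gliaquant import (
    SimulationParams,
    deg_filter_overlap,
    doublet_cluster_filter,
    generate_composition,
    generate_deg_tables,
    knn_kl_variability,
    proportion_anova_holm,
    qc_filter,
)
from statsmodels.stats.multitest import multipletests

from conftest import brute_force_holm


def make_adata(x, mito=None, **obs):
    x = np.asarray(x)
    n_cells, n_genes = x.shape
    var = pd.DataFrame(index=[f"g{i}" for i in range(n_genes)])
    var["mito"] = np.zeros(n_genes, bool) if mito is None else np.asarray(mito)
    obs_df = pd.DataFrame(obs, index=[f"c{i}" for i in range(n_cells)])
    return ad.AnnData(X=x.astype(float), obs=obs_df, var=var)


class TestQCFilter:
    def test_gene_detected_in_too_few_cells_removed(self):
        # gene 0 detected in 2 cells only (threshold 3)
        x = np.ones((4, 5))
        x[2:, 0] = 0
        adata = make_adata(x)
        out, report = qc_filter(adata, min_cells_per_gene=3, min_genes=0,
                                min_umi=0, max_umi=10**9, max_mito_frac=1.0)
        assert report["genes_removed_low_detection"] == 1
        assert "g0" not in out.var_names

    def test_mito_fraction_strictly_above(self):
        # 100 UMIs per cell; cell 0 has 6 mito (0.06 > 0.05: removed),
        # cell 1 has exactly 5 (0.05: retained)
        x = np.zeros((3, 4))
        x[:, :3] = [[94, 0, 0], [95, 0, 0], [100, 0, 0]]
        x[0, 3], x[1, 3], x[2, 3] = 6, 5, 0
        out, report = qc_filter(
            make_adata(x, mito=[False, False, False, True]),
            min_cells_per_gene=0, min_genes=0, min_umi=0, max_umi=10**9,
            max_mito_frac=0.05)
        assert report["cells_removed_high_mito"] == 1
        assert out.n_obs == 2 and "c0" not in out.obs_names

    def test_umi_window_strict(self):
        x = np.diag([499, 500, 30000, 30001]).astype(float)
        out, report = qc_filter(make_adata(x), min_cells_per_gene=0,
                                min_genes=0, min_umi=500, max_umi=30000,
                                max_mito_frac=1.0)
        assert report["cells_removed_low_umi"] == 1
        assert report["cells_removed_high_umi"] == 1
        assert set(out.obs_names) == {"c1", "c2"}

    def test_permissive_thresholds_are_identity(self):
        rng = np.random.default_rng(0)
        adata = make_adata(rng.poisson(2, (10, 8)))
        out, _ = qc_filter(adata, min_cells_per_gene=0, min_genes=0,
                           min_umi=0, max_umi=10**9, max_mito_frac=1.0)
        assert out.shape == adata.shape
        np.testing.assert_array_equal(np.asarray(out.X), np.asarray(adata.X))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(5, (60, 40))
        adata = make_adata(x, mito=rng.random(40) < 0.1)
        once, _ = qc_filter(adata, min_cells_per_gene=3, min_genes=5,
                            min_umi=100, max_umi=400, max_mito_frac=0.2)
        twice, report = qc_filter(once, min_cells_per_gene=3, min_genes=5,
                                  min_umi=100, max_umi=400, max_mito_frac=0.2)
        assert twice.shape == once.shape
        assert report["cells_removed_total"] == 0

    def test_everything_filtered_raises(self):
        with pytest.raises(ValueError):
            qc_filter(make_adata(np.ones((3, 3))), min_umi=10**6)


class TestDoubletClusterFilter:
    def obs(self, sizes_doublets):
        rows = []
        for cid, (n, nd) in sizes_doublets.items():
            for i in range(n):
                rows.append({"cluster_id": cid, "doublet": i < nd})
        return pd.DataFrame(rows)

    def test_majority_doublet_cluster_removed(self):
        retained, removed = doublet_cluster_filter(self.obs({"A": (10, 6),
                                                             "B": (10, 0)}))
        assert removed == ["A"]
        assert set(retained.cluster_id) == {"B"}

    def test_exactly_half_retained(self):
        retained, removed = doublet_cluster_filter(self.obs({"A": (10, 5)}))
        assert removed == []
        assert len(retained) == 10  # flagged cells kept with their cluster

    def test_no_doublets_identity(self):
        obs = self.obs({"A": (5, 0), "B": (7, 0)})
        retained, removed = doublet_cluster_filter(obs)
        assert removed == []
        pd.testing.assert_frame_equal(retained, obs)


class TestProportionAnova:
    def comp_from_props(self, props_by_sample, total=1000):
        idx = list(props_by_sample)
        return pd.DataFrame(
            [np.round(np.asarray(p) * total).astype(int)
             for p in props_by_sample.values()],
            index=idx, columns=["t1", "t2"])

    def test_f_matches_sums_of_squares_oracle(self):
        """Groups (1,2,3),(2,3,4),(3,4,5) (as proportions of a fixed total):
        SS_between = 6 (df 2), SS_within = 6 (df 6) -> F = 3."""
        vals = {"a1": 1, "a2": 2, "a3": 3,
                "b1": 2, "b2": 3, "b3": 4,
                "c1": 3, "c2": 4, "c3": 5}
        comp = pd.DataFrame({"t1": [v * 10 for v in vals.values()],
                             "t2": [100 - v * 10 for v in vals.values()]},
                            index=list(vals))
        gmap = pd.Series([k[0] for k in vals], index=list(vals))
        res = proportion_anova_holm(comp, gmap)
        assert res.loc[res.cell_type == "t1", "F"].iloc[0] == \
            pytest.approx(3.0, abs=1e-9)

    def test_identical_proportions_give_f_zero(self):
        comp = pd.DataFrame({"t1": [100] * 4, "t2": [900] * 4},
                            index=list("wxyz"))
        gmap = pd.Series(["A", "A", "B", "B"], index=list("wxyz"))
        res = proportion_anova_holm(comp, gmap)
        np.testing.assert_allclose(res["F"], 0.0, atol=1e-12)

    def test_holm_adjustment_values(self):
        # raw (0.01, 0.04, 0.03) -> Holm (0.03, 0.06, 0.06)
        adj = multipletests([0.01, 0.04, 0.03], method="holm")[1]
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
        np.testing.assert_allclose(adj, brute_force_holm([0.01, 0.04, 0.03]))

    def test_holm_matches_brute_force_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(2, 12))
            np.testing.assert_allclose(multipletests(p, method="holm")[1],
                                       brute_force_holm(p), atol=1e-12)

    def test_single_sample_genotype_rejected(self):
        comp = pd.DataFrame({"t1": [1, 2, 3]}, index=["s1", "s2", "s3"])
        gmap = pd.Series(["A", "A", "B"], index=["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            proportion_anova_holm(comp, gmap)

    def test_planted_effect_detected(self):
        comp, gmap = generate_composition(SimulationParams(
            rng_seed=0, composition_by_group={"A": (0.6, 0.4),
                                              "B": (0.4, 0.6)}))
        res = proportion_anova_holm(comp, gmap)
        assert (res.p_holm < 0.05).all()


class TestKnnKl:
    def ring(self, n):
        theta = 2 * np.pi * np.arange(n) / n
        return np.column_stack([np.cos(theta), np.sin(theta)])

    def test_perfectly_interleaved_labels_give_zero(self):
        """Alternating labels around a ring with k divisible by 4: every
        punctured +/- k/2 window is split 50/50, exactly the global
        distribution, so KL = 0."""
        n = 64
        labels = np.array(["A", "B"] * (n // 2))
        res = knn_kl_variability(self.ring(n), labels, k=32,
                                 n_permutations=0, seed=0)
        np.testing.assert_allclose(res.kl, 0.0, atol=1e-12)

    def test_interleaved_residual_at_k30_is_analytic(self):
        """With k = 30 (k/2 odd) the punctured window holds 14 same-label
        and 16 opposite-label cells, so every cell scores exactly
        KL((14/30,16/30) || (1/2,1/2))."""
        n = 64
        labels = np.array(["A", "B"] * (n // 2))
        res = knn_kl_variability(self.ring(n), labels, k=30,
                                 n_permutations=0, seed=0)
        p = np.array([14 / 30, 16 / 30])
        expected = (p * np.log(p / 0.5)).sum()
        np.testing.assert_allclose(res.kl, expected, atol=1e-12)

    def test_pure_neighborhood_kl_is_ln2(self):
        """A cell whose 30 neighbors are all sample A under q = (1/2, 1/2)
        scores KL = 1*ln(1/0.5) = ln 2."""
        n = 64
        half = np.zeros((n, 2))
        half[: n // 2, 0] = np.linspace(0, 1, n // 2)      # cluster A near x
        half[n // 2:, 0] = np.linspace(100, 101, n // 2)   # cluster B far
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        res = knn_kl_variability(half, labels, k=30, n_permutations=0, seed=0)
        np.testing.assert_allclose(res.kl, np.log(2), atol=1e-12)

    def test_kl_nonnegative_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=(80, 3))
            labels = rng.choice(["a", "b", "c"], 80)
            res = knn_kl_variability(x, labels, k=15, n_permutations=3,
                                     seed=1)
            assert (res.kl >= 0).all()
            assert (res.control_kl >= 0).all()

    def test_planted_separation_exceeds_shuffled_controls(self):
        """Two sample-segregated Gaussian clouds: observed mean KL beats the
        95th percentile of control means."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(0, 1, (60, 2)),
                                rng.normal(5, 1, (60, 2))])
            labels = np.array(["A"] * 60 + ["B"] * 60)
            res = knn_kl_variability(x, labels, k=30, n_permutations=50,
                                     seed=seed)
            wins += res.kl.mean() > np.quantile(res.control_means, 0.95)
        assert wins / 20 >= 0.95

    def test_control_shapes_and_seeding(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(50, 2))
        labels = rng.choice(["a", "b"], 50)
        r1 = knn_kl_variability(x, labels, k=10, n_permutations=7, seed=3)
        r2 = knn_kl_variability(x, labels, k=10, n_permutations=7, seed=3)
        assert r1.control_kl.shape == (7, 50)
        np.testing.assert_array_equal(r1.control_kl, r2.control_kl)

    def test_k_and_label_validation(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            knn_kl_variability(x, ["a"] * 10, k=10)
        with pytest.raises(ValueError):
            knn_kl_variability(x, ["a"] * 10, k=3)


class TestDegOverlap:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "fdr"])

    def test_simple_sets(self):
        study = self.table([("a", 1, 0.001), ("b", 1, 0.001), ("x", 0.1, 0.5)])
        ref = self.table([("b", 1, 0.001), ("c", 1, 0.001)])
        res = deg_filter_overlap(study, ref)
        assert (res["n_shared"], res["n_ref_only"], res["n_study_only"]) == \
            (1, 1, 1)
        assert res["shared_genes"] == ["b"]

    def test_counts_are_consistent_partitions(self):
        ref, study = generate_deg_tables(SimulationParams(rng_seed=4))
        res = deg_filter_overlap(study, ref)
        assert res["n_shared"] + res["n_ref_only"] == 461
        assert res["n_shared"] + res["n_study_only"] == 488

    def test_strict_threshold_boundaries(self):
        study = self.table([("at_lfc", 0.25, 0.001), ("at_fdr", 1.0, 0.01),
                            ("in", 0.26, 0.009)])
        res = deg_filter_overlap(study, ["in"])
        assert res["n_study_only"] == 0 and res["n_shared"] == 1

    def test_reference_as_gene_collection(self):
        study = self.table([("a", 1, 0.001)])
        res = deg_filter_overlap(study, [" a ", "b"])  # whitespace trimmed
        assert res["n_shared"] == 1 and res["n_ref_only"] == 1

    def test_duplicate_symbols_rejected(self):
        study = self.table([("a", 1, 0.001), ("a ", 2, 0.001)])
        with pytest.raises(ValueError, match="duplicate"):
            deg_filter_overlap(study, ["b"])
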