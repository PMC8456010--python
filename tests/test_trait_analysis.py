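"""Trait selection, PCA, silhouette, ecotype clustering, LS means."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nichepheno as nf
from nichepheno import trait_analysis as ta


def anova_oracle(values: np.ndarray, groups: np.ndarray):
    """Brute-force one-way ANOVA: partial R^2 = SSB/SST and the F ratio."""
    grand = values.mean()
    sst = ((values - grand) ** 2).sum()
    ssb = sum(len(values[groups == g]) *
              (values[groups == g].mean() - grand) ** 2
              for g in np.unique(groups))
    ssw = sst - ssb
    g = len(np.unique(groups))
    n = len(values)
    F = (ssb / (g - 1)) / (ssw / (n - g))
    return ssb / sst, F


class TestStepwiseDiscriminant:
    def test_first_step_equals_anova_oracle(self, toy_groups):
        res = ta.stepwise_discriminant(toy_groups, ["signal", "null"],
                                       sle=0.5, sls=0.5)
        first = res.entries.iloc[0]
        assert first["trait"] == "signal"
        rsq, F = anova_oracle(toy_groups["signal"].to_numpy(),
                              toy_groups["population_id"].to_numpy())
        assert first["partial_rsq"] == pytest.approx(rsq, abs=1e-8)
        assert first["F"] == pytest.approx(F, abs=1e-8)

    def test_equal_means_nothing_enters(self, rng):
        df = pd.DataFrame({
            "population_id": np.repeat(list("ABC"), 10),
            "t1": np.tile(np.arange(10, dtype=float), 3),
            "t2": np.tile(np.arange(10, dtype=float) ** 2, 3),
        })
        res = ta.stepwise_discriminant(df, ["t1", "t2"], sle=0.05)
        assert res.entries.empty

    def test_signal_recovery_on_synthetic_study(self, small_study):
        traits = small_study[3]
        res = ta.stepwise_by_sex(traits, sle=0.05, sls=0.05)
        sel = res["hen"].selected
        signal = set(nf.synthetic_landscape.SIGNAL_TRAITS)
        assert len(set(sel) & signal) >= 5     # majority of signal traits

    def test_partial_rsq_in_unit_interval(self, small_study):
        res = ta.stepwise_by_sex(small_study[3], sle=0.15)
        for r in res.values():
            assert ((r.entries["partial_rsq"] >= 0)
                    & (r.entries["partial_rsq"] <= 1)).all()

    def test_singular_traits_named(self):
        df = pd.DataFrame({
            "population_id": np.repeat(list("AB"), 6),
            "t1": np.r_[np.arange(6.0), np.arange(6.0) + 1],
        })
        df["t2"] = df["t1"] * 2.0              # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="t1"):
            ta.stepwise_discriminant(df, ["t1", "t2"], sle=0.9, sls=0.95)


class TestPcaVariance:
    def test_two_perfectly_correlated_traits(self):
        x = np.arange(30, dtype=float)
        df = pd.DataFrame({"population_id": "A", "sex": "hen",
                           "t1": x, "t2": 3.0 * x + 1.0})
        out = ta.pca_variance(df, ["t1", "t2"])
        assert out["proportion"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_proportions_sum_to_one(self, small_study):
        out = ta.pca_variance(small_study[3])
        assert out["proportion"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out["cumulative"].iloc[-1] == pytest.approx(1.0, abs=1e-9)

    def test_column_order_invariance(self, small_study):
        traits = small_study[3]
        cols = ta.trait_columns(traits)
        a = ta.pca_variance(traits, cols)
        b = ta.pca_variance(traits, cols[::-1])
        assert np.allclose(a["proportion"], b["proportion"], atol=1e-10)

    def test_matches_sklearn_on_standardized_data(self, small_study):
        from sklearn.decomposition import PCA
        traits = small_study[3]
        cols = ta.trait_columns(traits)
        X = traits[cols].to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        skl = PCA().fit(Xs).explained_variance_ratio_
        ours = ta.pca_variance(traits, cols)["proportion"].to_numpy()
        assert np.allclose(ours, skl, atol=1e-8)

    def test_constant_trait_dropped(self):
        df = pd.DataFrame({"population_id": "A", "sex": "hen",
                           "t1": np.arange(10.0), "t2": 1.0,
                           "t3": np.arange(10.0) ** 1.5})
        with pytest.warns(UserWarning, match="constant"):
            out = ta.pca_variance(df, ["t1", "t2", "t3"])
        assert len(out) == 2


class TestSilhouette:
    def test_hand_computed_four_points(self):
        """Two clusters of two points; silhouette from the definition."""
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([1, 1, 2, 2])
        s = ta.silhouette_widths(X, labels)
        # point 0: a = 1, b = mean(10, 11) = 10.5 -> (10.5-1)/10.5
        assert s[0] == pytest.approx((10.5 - 1.0) / 10.5, abs=1e-12)
        from sklearn.metrics import silhouette_samples
        assert np.allclose(s, silhouette_samples(X, labels), atol=1e-10)

    def test_coincident_clusters_limit(self):
        X = np.array([[0.0], [0.0], [9.0], [9.0]])
        s = ta.silhouette_widths(X, np.array([1, 1, 2, 2]))
        assert np.allclose(s, 1.0)

    def test_three_blob_best_k(self, rng):
        X = np.vstack([rng.normal(c, 0.15, (8, 3))
                       for c in (0.0, 3.0, 6.0)])
        M = pd.DataFrame(X, index=[f"P{i}" for i in range(24)])
        best, curve = ta.silhouette_scan(M, range(2, 7))
        assert best == 3
        assert curve["mean_silhouette"].between(-1, 1).all()

    def test_too_few_populations_rejected(self):
        M = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            ta.silhouette_scan(M, range(2, 4))


class TestClusterEcotypes:
    def test_zero_noise_perfect_recovery(self):
        from sklearn.metrics import adjusted_rand_score
        cfg = nf.LandscapeConfig(grid_shape=(60, 60), n_layers=6,
                                 noise_sd=0.0, smooth_amplitude=0.0,
                                 correlated_pairs=())
        _, sites, truth, traits = nf.simulate_study(cfg)
        M = ta.population_means(traits, list(truth.trait_functions)[:8],
                                sex="hen")
        assign = ta.cluster_ecotypes(M, k=3)
        true = [truth.ecotype_of_pop[p] for p in assign.labels.index]
        assert adjusted_rand_score(true, assign.labels.to_numpy()) == 1.0

    def test_default_noise_recovery(self, small_study):
        from sklearn.metrics import adjusted_rand_score
        _, sites, truth, traits = small_study
        sel = ta.stepwise_by_sex(traits, sle=0.05)["hen"].selected
        M = ta.population_means(traits, sel, sex="hen")
        assign = ta.cluster_ecotypes(M, k=3)
        true = [truth.ecotype_of_pop[p] for p in assign.labels.index]
        assert adjusted_rand_score(true, assign.labels.to_numpy()) >= 0.8

    def test_k_one_single_cluster(self, small_study):
        M = ta.population_means(small_study[3], sex="hen")
        assign = ta.cluster_ecotypes(M, k=1)
        assert assign.labels.nunique() == 1

    def test_k_exceeding_populations_rejected(self, small_study):
        M = ta.population_means(small_study[3], sex="hen")
        with pytest.raises(ValueError):
            ta.cluster_ecotypes(M, k=27)

    def test_ari_is_relabeling_invariant(self, small_study):
        from sklearn.metrics import adjusted_rand_score
        M = ta.population_means(small_study[3], sex="hen")
        assign = ta.cluster_ecotypes(M, k=3)
        lab = assign.labels.to_numpy()
        permuted = np.select([lab == 1, lab == 2, lab == 3], [3, 1, 2])
        assert adjusted_rand_score(lab, permuted) == 1.0

    def test_ac_reported_for_all_linkages(self, small_study):
        M = ta.population_means(small_study[3], sex="hen")
        assign = ta.cluster_ecotypes(M, k=3)
        assert set(assign.ac_by_method) == set(ta.LINKAGES)
        assert all(0.0 <= v <= 1.0 for v in assign.ac_by_method.values())


class TestLsmeans:
    def _eco(self, traits):
        pops = sorted(traits["population_id"].unique())
        return pd.Series([i % 3 + 1 for i in range(len(pops))],
                         index=pops)

    def test_balanced_design_equals_group_means(self, small_study):
        traits = small_study[3]
        eco = self._eco(traits)
        out = ta.lsmeans(traits, "BW", eco, sex="hen")
        df = traits[traits["sex"] == "hen"].copy()
        df["e"] = df["population_id"].map(eco)
        for _, row in out.iterrows():
            raw = df[df["e"] == row["ecotype"]]["BW"].mean()
            assert row["lsmean"] == pytest.approx(raw, abs=1e-10)

    def test_zero_noise_exact_shifts(self):
        cfg = nf.LandscapeConfig(grid_shape=(60, 60), n_layers=6,
                                 noise_sd=0.0, smooth_amplitude=0.0,
                                 correlated_pairs=(),
                                 effect_sizes=(1.0,) * 8)
        _, sites, truth, traits = nf.simulate_study(cfg)
        eco = pd.Series(truth.ecotype_of_pop)
        out = ta.lsmeans(traits, "BW", eco, sex="hen")
        m = out.set_index("ecotype")["lsmean"]
        assert m[2] - m[1] == pytest.approx(1.0, abs=1e-10)
        assert m[3] - m[1] == pytest.approx(2.0, abs=1e-10)

    def test_identical_groups_share_letters(self, rng):
        df = pd.DataFrame({
            "population_id": np.repeat(list("ABCDEF"), 10),
            "sex": "hen",
            "t": np.tile(rng.normal(0, 1, 10), 6),
        })
        eco = pd.Series([1, 1, 2, 2, 3, 3], index=list("ABCDEF"))
        out = ta.lsmeans(df, "t", eco, sex="hen")
        assert out["letters"].nunique() == 1

    def test_significant_separation_gets_distinct_letters(self):
        cfg = nf.LandscapeConfig(grid_shape=(60, 60), n_layers=6,
                                 correlated_pairs=())
        _, sites, truth, traits = nf.simulate_study(cfg)
        eco = pd.Series(truth.ecotype_of_pop)
        out = ta.lsmeans(traits, "BW", eco, sex="hen")
        assert out["letters"].nunique() >= 2
        assert out.attrs["anova_p"] < 0.001

    def test_full_table_layout(self, small_study):
        traits = small_study[3]
        eco = self._eco(traits)
        table = ta.lsmeans_table(traits, ["BW", "BL"], eco)
        assert set(table["sex"]) == {"hen", "cock"}
        assert set(table["trait"]) == {"BW", "BL"}
        assert len(table) == 12               # 3 ecotypes x 2 sexes x 2
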