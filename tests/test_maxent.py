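"""MaxEnt core: features, fitting, prediction, AICc, tuning, importance."""

import numpy as np
import pandas as pd
import pytest

import nichepheno as nf
from nichepheno import geodata as gd
from nichepheno import maxent as mx


@pytest.fixture(scope="module")
def bg3(sdm_inputs=None):
    rng = np.random.default_rng(3)
    return pd.DataFrame({"a": rng.uniform(0, 10, 200),
                         "b": rng.uniform(-5, 5, 200),
                         "c": rng.uniform(0, 1, 200)})


class TestBuildFeatures:
    def test_minmax_scaling(self):
        bg = pd.DataFrame({"a": [0.0, 10.0]})
        fs = mx.build_features(bg, ["a"], "L")
        F = fs.transform(bg)
        assert F[:, 0].tolist() == [0.0, 1.0]

    def test_lq_combo_counts(self, bg3):
        fs = mx.build_features(bg3, ["a", "b", "c"], "LQ")
        assert len(fs.features) == 6          # 3 L + 3 Q

    def test_product_counts(self, bg3):
        fs = mx.build_features(bg3, ["a", "b", "c"], "P")
        assert len(fs.features) == 3          # 3 choose 2

    def test_hinge_threshold_counts_and_range(self, bg3):
        fs = mx.build_features(bg3, ["a"], "HT", n_knots=5)
        kinds = [f.kind for f in fs.features]
        assert kinds.count("T") == 5 and kinds.count("H") == 10
        F = fs.transform(bg3)
        assert F.min() >= 0.0 and F.max() <= 1.0
        lo, hi = bg3["a"].min(), bg3["a"].max()
        for f in fs.features:
            if f.knot is not None:
                assert lo < f.knot < hi

    def test_constant_layer_dropped(self):
        bg = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            fs = mx.build_features(bg, ["a", "b"], "L")
        assert fs.layers == ["b"]

    def test_all_features_unit_interval(self, bg3):
        fs = mx.build_features(bg3, ["a", "b", "c"], "LQPHT", n_knots=6)
        F = fs.transform(bg3)
        assert F.min() >= 0.0 and F.max() <= 1.0


class TestFitMaxent:
    def test_full_shrinkage_limit(self, bg3):
        fs = mx.build_features(bg3, ["a", "b"], "LQ")
        m = mx.fit_maxent(fs.transform(bg3.iloc[:10]), fs.transform(bg3),
                          rm=1e9, feature_set=fs)
        assert m.k == 0
        assert m.entropy == pytest.approx(np.log(len(bg3)))
        assert np.all(m.predict(bg3, "logistic") == 0.5)

    def test_objective_monotone_nondecreasing(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        layers = ["bio01", "bio02", "bio03"]
        fs = mx.build_features(cells, layers, "LQH", n_knots=6)
        m = mx.fit_maxent(fs.transform(pres), fs.transform(cells), 1.0, fs)
        diffs = np.diff(m.objective_trace)
        assert (diffs >= -1e-12).all()

    def test_raw_normalizes_over_background(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        fs = mx.build_features(cells, ["bio01", "bio04"], "LQ")
        m = mx.fit_maxent(fs.transform(pres), fs.transform(cells), 1.0, fs)
        assert m.raw(cells).sum() == pytest.approx(1.0, abs=1e-9)

    def test_logistic_monotone_in_raw(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        fs = mx.build_features(cells, ["bio01", "bio04"], "LQ")
        m = mx.fit_maxent(fs.transform(pres), fs.transform(cells), 1.0, fs)
        raw = m.predict(cells, "raw")
        logi = m.predict(cells, "logistic")
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= -1e-15).all()
        assert logi.min() >= 0.0 and logi.max() <= 1.0

    def test_exponential_truth_recovery(self, sdm_inputs):
        """Presences from suitability ~ exp(2 * scaled layer)."""
        _, _, _, cells = sdm_inputs
        z = cells["bio01"].to_numpy()
        z = (z - z.min()) / (z.max() - z.min())
        w = np.exp(2.0 * z)
        rng = np.random.default_rng(42)
        idx = rng.choice(len(cells), 300, p=w / w.sum())
        pres = cells.iloc[idx]
        fs = mx.build_features(cells, ["bio01", "bio04"], "L")
        m = mx.fit_maxent(fs.transform(pres), fs.transform(cells), 1.0, fs)
        lam = {f.layer: l for f, l in zip(fs.features, m.lam)}
        assert lam["bio01"] > 0
        pred = m.predict(cells, "raw")
        assert np.corrcoef(pred, w)[0, 1] >= 0.9

    def test_needs_presences_and_background(self, bg3):
        fs = mx.build_features(bg3, ["a"], "L")
        with pytest.raises(ValueError):
            mx.fit_maxent(fs.transform(bg3.iloc[:0]), fs.transform(bg3),
                          1.0, fs)


class TestGainAicc:
    def test_uniform_model_gain_zero(self, bg3):
        fs = mx.build_features(bg3, ["a"], "L")
        m = mx.fit_maxent(fs.transform(bg3.iloc[:5]), fs.transform(bg3),
                          rm=1e9, feature_set=fs)
        assert mx.gain(m, fs.transform(bg3.iloc[:5])) == pytest.approx(0.0)

    def test_training_gain_nonnegative(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        fs = mx.build_features(cells, ["bio01", "bio02"], "LQ")
        Fp = fs.transform(pres)
        m = mx.fit_maxent(Fp, fs.transform(cells), 1.0, fs)
        assert mx.gain(m, Fp) >= -1e-9

    def test_empty_presence_error(self, bg3):
        fs = mx.build_features(bg3, ["a"], "L")
        m = mx.fit_maxent(fs.transform(bg3.iloc[:5]), fs.transform(bg3),
                          1.0, fs)
        with pytest.raises(ValueError):
            mx.gain(m, fs.transform(bg3.iloc[:0]))

    def test_uniform_aicc_closed_form(self, bg3):
        fs = mx.build_features(bg3, ["a"], "L")
        m = mx.fit_maxent(fs.transform(bg3.iloc[:5]), fs.transform(bg3),
                          rm=1e9, feature_set=fs)
        n, N = 7, len(bg3)
        k, ll, v = mx.aicc(m, fs.transform(bg3.iloc[:n]),
                           fs.transform(bg3))
        assert k == 0
        assert ll == pytest.approx(-n * np.log(N), rel=1e-12)
        assert v == pytest.approx(2 * n * np.log(N), rel=1e-12)

    def test_hand_computed_aicc_four_cells(self):
        """k=1 model on a 4-cell grid, 3 occurrences, by direct formula."""
        cells = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
        fs = mx.build_features(cells, ["a"], "L")
        Fc = fs.transform(cells)
        m = mx.MaxEntModel(fs, np.array([1.5]), 1.0, np.array([0.1]),
                           ln_z=0.0, entropy=0.0, n_background=4,
                           converged=True)
        occ = Fc[[1, 2, 3]]
        k, ll, v = mx.aicc(m, occ, Fc)
        eta = 1.5 * Fc[:, 0]
        p = np.exp(eta) / np.exp(eta).sum()
        ll_exp = np.log(p[[1, 2, 3]]).sum()
        assert k == 1
        assert ll == pytest.approx(ll_exp, rel=1e-12)
        assert v == pytest.approx(2 * 1 - 2 * ll_exp + 2 * 1 * 2 / (3 - 2))

    def test_zero_coefficient_feature_leaves_aicc_unchanged(self, bg3):
        fs1 = mx.build_features(bg3, ["a"], "L")
        fs2 = mx.build_features(bg3, ["a", "c"], "L")
        occ = bg3.iloc[:20]
        m1 = mx.MaxEntModel(fs1, np.array([2.0]), 1.0, np.array([0.1]),
                            0.0, 0.0, len(bg3), True)
        m2 = mx.MaxEntModel(fs2, np.array([2.0, 0.0]), 1.0,
                            np.array([0.1, 0.1]), 0.0, 0.0, len(bg3), True)
        a1 = mx.aicc(m1, fs1.transform(occ), fs1.transform(bg3))
        a2 = mx.aicc(m2, fs2.transform(occ), fs2.transform(bg3))
        assert a1[2] == pytest.approx(a2[2], rel=1e-12)


class TestTune:
    def test_single_cell_grid(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        res = mx.tune(pres, cells, ["bio01", "bio02"], cells,
                      combos=("LQ",), rm_values=(1.0,), n_knots=4)
        assert len(res.table) == 1
        assert res.table["deltaAICc"].iloc[0] == 0.0

    def test_empty_grid_rejected(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        with pytest.raises(ValueError):
            mx.tune(pres, cells, ["bio01"], cells, combos=(),
                    rm_values=(1.0,))

    def test_default_grid_cardinality(self):
        assert len(mx.DEFAULT_COMBOS) * len(mx.DEFAULT_RMS) == 48

    def test_selected_row_minimizes_aicc(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        res = mx.tune(pres, cells, ["bio01", "bio02"], cells,
                      combos=("L", "LQ"), rm_values=(0.5, 2.0), n_knots=4)
        assert len(res.table) == 4
        assert res.selected["deltaAICc"] == 0.0
        assert res.table["AICc"].min() == res.selected["AICc"]


class TestBlockPartition:
    def test_four_quadrants(self):
        coords = pd.DataFrame({"lon": [0.0, 0.0, 1.0, 1.0],
                               "lat": [0.0, 1.0, 0.0, 1.0]})
        labels = mx.block_partition(coords, k=4)
        assert sorted(labels) == [1, 2, 3, 4]

    def test_balanced_fold_sizes(self, rng):
        coords = pd.DataFrame({"lon": rng.uniform(0, 1, 40),
                               "lat": rng.uniform(0, 1, 40)})
        labels = mx.block_partition(coords, k=4)
        sizes = pd.Series(labels).value_counts()
        assert sizes.max() - sizes.min() <= 2

    def test_deterministic(self, rng):
        coords = pd.DataFrame({"lon": rng.uniform(0, 1, 30),
                               "lat": rng.uniform(0, 1, 30)})
        a = mx.block_partition(coords, k=4)
        b = mx.block_partition(coords, k=4)
        assert np.array_equal(a, b)

    def test_degenerate_geometry_rejected(self):
        coords = pd.DataFrame({"lon": [1.0] * 8, "lat": [2.0] * 8})
        with pytest.raises(ValueError):
            mx.block_partition(coords, k=4)


class TestImportance:
    def test_single_variable_gets_all_contribution(self, sdm_inputs):
        _, _, _, cells = sdm_inputs
        z = cells["bio01"].to_numpy()
        z = (z - z.min()) / (z.max() - z.min())
        w = np.exp(2.0 * z)
        rng = np.random.default_rng(8)
        pres = cells.iloc[rng.choice(len(cells), 200, p=w / w.sum())]
        fs = mx.build_features(cells, ["bio01"], "LQ")
        m = mx.fit_maxent(fs.transform(pres), fs.transform(cells), 1.0, fs)
        assert m.k > 0
        pct = mx.percent_contribution(m)
        assert pct["bio01"] == pytest.approx(100.0, abs=0.1)

    def test_contributions_sum_to_100(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        fs = mx.build_features(cells, ["bio01", "bio02", "bio04"], "LQH",
                               n_knots=5)
        m = mx.fit_maxent(fs.transform(pres), fs.transform(cells), 1.0, fs)
        pct = mx.percent_contribution(m)
        assert pct.sum() == pytest.approx(100.0, abs=0.1)
        assert (pct >= 0).all()

    def test_jackknife_nesting_and_redundancy(self, sdm_inputs):
        _, truth, pres, cells = sdm_inputs
        cells2 = cells.copy()
        cells2["dup"] = cells2["bio01"]          # exact duplicate layer
        pres2 = pres.copy()
        pres2["dup"] = pres2["bio01"]
        layers = ["bio01", "dup", "bio04"]
        jk = mx.jackknife(layers, pres2, cells2, combo="LQ", rm=1.0)
        assert (jk["gain_without"] <= jk["gain_full"] + 1e-6).all()
        assert jk["gain_full"].nunique() == 1
        # removing one duplicate costs (almost) nothing
        assert abs(jk.loc["dup", "gain_without"]
                   - jk.loc["dup", "gain_full"]) < 0.01

    def test_jackknife_needs_two_variables(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        with pytest.raises(ValueError):
            mx.jackknife(["bio01"], pres, cells)


class TestSelectVariables:
    def test_perfectly_correlated_copy_collapses(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        cells2 = cells.copy()
        cells2["copy"] = cells2["bio01"]
        pres2 = pres.copy()
        pres2["copy"] = pres2["bio01"]
        kept = mx.select_variables(pres2, cells2, ["bio01", "copy"],
                                   contrib_thresh=0.0, combo="LQ")
        assert len(kept) == 1

    def test_disabled_filters_keep_everything(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        layers = ["bio01", "bio02", "bio04"]
        kept = mx.select_variables(pres, cells, layers, corr_thresh=1.1,
                                   contrib_thresh=0.0, combo="LQ")
        assert sorted(kept) == sorted(layers)

    def test_all_eliminated_raises(self, sdm_inputs):
        _, _, pres, cells = sdm_inputs
        with pytest.raises(ValueError, match="relax"):
            mx.select_variables(pres, cells, ["bio01", "bio02"],
                                contrib_thresh=101.0, combo="LQ")


class TestRecoverySmoke:
    def test_suitability_recovery_single_seed(self, sdm_inputs):
        """Logistic prediction tracks the generating suitability."""
        stack, truth, pres, cells = sdm_inputs
        fs = mx.build_features(cells, truth.true_variable_set, "LQH",
                               n_knots=8)
        m = mx.fit_maxent(fs.transform(pres), fs.transform(cells), 1.0, fs)
        pred = m.predict(cells, "logistic")
        tv = truth.true_suitability[cells["row"].to_numpy(),
                                    cells["col"].to_numpy()]
        # single-seed sanity bound; the 10-seed median contract lives in
        # the acceptance suite
        assert np.corrcoef(pred, tv)[0, 1] >= 0.6
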