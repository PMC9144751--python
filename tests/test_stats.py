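"""Statistical surface: rank tests, ANOVA + post hoc, PCA, correlations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenoprime import (
    GrowthScenario,
    compute_trait_table,
    heatmap_matrix,
    kruskal_auc,
    metabolite_anova,
    pca_metabolites,
    pca_svd,
    pearson_matrix,
    simulate_growth,
    simulate_metabolites,
)
from phenoprime.simulate import default_metabolite_panel
from phenoprime.stats import MetaboliteTable, StatsError


@pytest.fixture(scope="module")
def metabolite_table():
    groups = [
        (t, c, cond)
        for cond in ("optimal", "salt")
        for t, c in [("control", 0.0), ("DAP", 1.0), ("Put", 0.1)]
    ]
    names, classes, baselines = default_metabolite_panel()
    effects = np.zeros((len(groups), len(names)))
    effects[1, 0] = np.log(2.0)  # DAP optimal doubles the first metabolite
    return simulate_metabolites(
        groups, n_per_group=4, metabolites=names, classes=classes,
        effects=effects, baselines=baselines, noise_sd=0.15, seed=21,
    )


class TestKruskalAUC:
    def test_identical_groups_not_significant(self):
        table = pd.DataFrame(
            {
                "treatment": ["control"] * 6 + ["DAP"] * 6,
                "concentration": [0.0] * 6 + [1.0] * 6,
                "condition": "optimal",
                "auc": [10.0, 11.0, 12.0, 13.0, 14.0, 15.0] * 2,
            }
        )
        res = kruskal_auc(table, "optimal")
        assert len(res) == 1
        assert res["p_value"].iloc[0] > 0.9
        assert not res["significant"].iloc[0]

    def test_obvious_shift_is_significant(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "treatment": ["control"] * 20 + ["DAP"] * 20,
                "concentration": [0.0] * 20 + [1.0] * 20,
                "condition": "salt",
                "auc": np.concatenate(
                    [rng.normal(100, 5, 20), rng.normal(200, 5, 20)]
                ),
            }
        )
        res = kruskal_auc(table, "salt")
        assert res["significant"].iloc[0]

    def test_missing_control_raises(self):
        table = pd.DataFrame(
            {
                "treatment": ["DAP"] * 4,
                "concentration": 1.0,
                "condition": "salt",
                "auc": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(StatsError, match="control"):
            kruskal_auc(table, "salt")

    def test_one_row_per_treatment(self, small_scenario):
        table = compute_trait_table(simulate_growth(small_scenario))
        res = kruskal_auc(table, "osmotic")
        assert len(res) == 6
        assert set(res["treatment"]) == {"DAP", "Orn", "Put"}


class TestMetaboliteAnova:
    def test_planted_effect_detected(self, metabolite_table):
        res = metabolite_anova(metabolite_table)
        first = metabolite_table.values.columns[0]
        row = res.anova.query("condition == 'optimal' and metabolite == @first")
        assert row["significant"].iloc[0]
        ph = res.posthoc.query(
            "condition == 'optimal' and metabolite == @first and treatment == 'DAP'"
        )
        assert ph["significant"].iloc[0]

    def test_tukey_matches_scipy_reference(self, metabolite_table):
        res = metabolite_anova(metabolite_table)
        lnv = metabolite_table.log_values()
        meta = metabolite_table.meta
        met = metabolite_table.values.columns[3]
        sel = meta["condition"] == "optimal"
        labels = meta.loc[sel, "treatment"]
        groups = [lnv.loc[sel][labels == t][met].to_numpy()
                  for t in ("control", "DAP", "Put")]
        ref = sps.tukey_hsd(*groups)
        mine = res.posthoc.query(
            "condition == 'optimal' and metabolite == @met"
        ).set_index("treatment")["p_value"]
        assert mine.loc["DAP"] == pytest.approx(float(ref.pvalue[1, 0]), rel=1e-9)
        assert mine.loc["Put"] == pytest.approx(float(ref.pvalue[2, 0]), rel=1e-9)

    def test_constant_metabolite_flagged_undefined(self):
        groups = [("control", 0.0, "optimal"), ("DAP", 1.0, "optimal")]
        names, classes, baselines = default_metabolite_panel()
        t = simulate_metabolites(groups, n_per_group=4, metabolites=names,
                                 classes=classes, baselines=baselines,
                                 noise_sd=0.0, seed=0)
        res = metabolite_anova(t)
        assert res.anova["undefined"].all()
        assert not res.anova["significant"].any()

    def test_duncan_flags_at_least_obvious_effect(self, metabolite_table):
        res = metabolite_anova(metabolite_table, posthoc="duncan")
        first = metabolite_table.values.columns[0]
        ph = res.posthoc.query(
            "condition == 'optimal' and metabolite == @first and treatment == 'DAP'"
        )
        assert ph["significant"].iloc[0]

    def test_two_way_terms_present(self, metabolite_table):
        res = metabolite_anova(metabolite_table, posthoc=None, two_way=True)
        tests = set(res.anova["test"])
        assert "anova-2way[C(group):C(condition)]" in tests


class TestPCA:
    def test_rank_one_data(self):
        u = np.arange(1, 9, dtype=float)
        X = pd.DataFrame(np.outer(u, [1.0, 2.0, 3.0]))
        res = pca_svd(X, scale=False)
        assert res.variance_explained[0] == pytest.approx(1.0)
        assert np.all(res.variance_explained[1:] < 1e-12)

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 8)))
        res = pca_svd(X, scale=True)
        Z = (X - X.mean()) / X.std(ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(Z.to_numpy(), rowvar=False)))[::-1]
        oracle = eigvals / eigvals.sum()
        np.testing.assert_allclose(res.variance_explained, oracle, atol=1e-8)

    def test_variance_fractions_sum_to_one_descending(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 6)))
        v = pca_svd(X).variance_explained
        assert v.sum() == pytest.approx(1.0)
        assert np.all(np.diff(v) <= 1e-12)

    def test_duplicating_samples_preserves_variance_fractions(self, rng):
        X = pd.DataFrame(rng.normal(size=(9, 5)))
        a = pca_svd(X).variance_explained
        b = pca_svd(pd.concat([X, X], ignore_index=True)).variance_explained
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 7)))
        res = pca_svd(X, scale=True)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        np.testing.assert_allclose(res.reconstruct(), Z, atol=1e-8)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        X["const"] = 1.0
        res = pca_svd(X, scale=True)
        assert res.dropped == ("const",)
        assert "const" not in res.loadings.index

    def test_group_mean_mode_has_one_score_per_group(self, metabolite_table):
        res = pca_metabolites(metabolite_table, group_means=True)
        assert res.scores.shape[0] == 6  # 3 treatments x 2 conditions


class TestPearson:
    def test_self_correlation_unit_diagonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)))
        res = pearson_matrix(X)
        np.testing.assert_allclose(np.diag(res.r), 1.0)

    def test_exact_negative_proportionality(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X = pd.DataFrame({"x": x, "y": -2 * x})
        res = pearson_matrix(X)
        assert res.r.loc["x", "y"] == pytest.approx(-1.0)
        assert res.p.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_r(self):
        X = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 3, 2, 4]})
        res = pearson_matrix(X)
        assert res.r.loc["x", "y"] == pytest.approx(0.8)
        ref = sps.pearsonr(X["x"], X["y"])
        assert res.p.loc["x", "y"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_symmetric_and_psd(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 6)))
        r = pearson_matrix(X).r.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        assert np.linalg.eigvalsh(r).min() > -1e-10

    def test_zero_variance_flagged_nan(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10), "c": np.ones(10)})
        res = pearson_matrix(X)
        assert np.isnan(res.r.loc["c", "x"])

    def test_too_few_samples(self):
        with pytest.raises(StatsError, match="3 samples"):
            pearson_matrix(pd.DataFrame({"x": [1, 2], "y": [3, 4]}))


class TestHeatmap:
    def test_group_of_twos_maps_to_ln2(self):
        names, classes, baselines = default_metabolite_panel()
        values = pd.DataFrame(
            2.0, index=[f"s{i}" for i in range(4)], columns=names
        )
        meta = pd.DataFrame(
            {"treatment": "control", "concentration": 0.0, "condition": "optimal"},
            index=values.index,
        )
        hm = heatmap_matrix(MetaboliteTable(values, meta, classes))
        np.testing.assert_allclose(hm.values.to_numpy(), np.log(2.0))

    def test_full_design_column_count(self):
        groups = [
            (t, c, cond)
            for cond in ("optimal", "osmotic", "salt")
            for t, c in [("control", 0.0), ("DAP", 0.1), ("DAP", 1.0),
                         ("Orn", 0.1), ("Orn", 1.0), ("Put", 0.1), ("Put", 1.0)]
        ]
        t = simulate_metabolites(groups, n_per_group=4, seed=3)
        hm = heatmap_matrix(t)
        assert hm.values.shape[1] == 21

    def test_rows_in_class_blocks(self, metabolite_table):
        hm = heatmap_matrix(metabolite_table)
        cls = list(hm.classes)
        # class labels appear in contiguous blocks
        seen = []
        for c in cls:
            if not seen or seen[-1] != c:
                seen.append(c)
        assert len(seen) == len(set(seen))

    def test_significance_dots_align(self, metabolite_table):
        res = metabolite_anova(metabolite_table)
        hm = heatmap_matrix(metabolite_table, res)
        first = metabolite_table.values.columns[0]
        assert hm.significant.loc[first, "1 mM DAP | optimal"]
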