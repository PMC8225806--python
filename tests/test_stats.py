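import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import anova_f_oracle, grid_count_area, kruskal_h_oracle
from woundtexture.errors import DegenerateInputError
from woundtexture.stats import (
    RATIO_TYPES,
    anderson_darling_pvalue,
    anova_tukey,
    compute_ratios,
    fit_pca,
    interval_summary,
    kruskal_wallis,
    normality_gate,
    polygon_area,
    predict_healing,
)
from woundtexture.synthetic import generate_wound_polygon
from woundtexture.texture import FEATURE_COLUMNS, FeatureVector


class TestPolygonArea:
    def test_unit_square(self):
        assert polygon_area(np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float)) == 1.0

    def test_triangle(self):
        assert polygon_area(np.array([(0, 0), (4, 0), (0, 3)], float)) == 6.0

    def test_orientation_independent(self):
        cw = np.array([(0, 0), (0, 1), (1, 1), (1, 0)], float)
        assert polygon_area(cw) == polygon_area(cw[::-1]) == 1.0

    def test_agrees_with_grid_counting(self, rng):
        """Shoelace area matches 0.01-resolution square counting to < 0.5%."""
        for i in range(50):
            poly = generate_wound_polygon(rng, rng.uniform(1.0, 3.0), (5.0, 5.0))
            exact = polygon_area(poly)
            grid = grid_count_area(poly.vertices, step=0.01)
            assert abs(grid - exact) / exact < 0.005

    def test_invalid_polygons_rejected(self):
        with pytest.raises(Exception):
            polygon_area(np.array([(0, 0), (1, 1)], float))
        with pytest.raises(Exception):  # bow-tie
            polygon_area(np.array([(0, 0), (1, 1), (1, 0), (0, 1)], float))


def _fv(values):
    return FeatureVector(*values)


class TestComputeRatios:
    def test_area_ratios(self):
        out = compute_ratios(areas_by_week={0: 10.0, 1: 8.0, 2: 5.0})
        assert out["w1_over_w0"].area_ratio == pytest.approx(0.8)
        assert out["w2_over_w1"].area_ratio == pytest.approx(0.625)
        assert out["w2_over_w0"].area_ratio == pytest.approx(0.5)

    def test_identical_features_give_unit_ratios(self):
        fv = _fv(np.linspace(0.5, 6.0, 12))
        out = compute_ratios(features_by_week={0: fv, 1: fv, 2: fv})
        for rt in RATIO_TYPES:
            np.testing.assert_allclose(out[rt].values, 1.0)
            assert out[rt].valid

    def test_chain_identity(self, rng):
        fvs = {w: _fv(rng.uniform(0.1, 5.0, 12)) for w in (0, 1, 2)}
        out = compute_ratios(features_by_week=fvs)
        np.testing.assert_allclose(
            out["w2_over_w0"].values,
            out["w2_over_w1"].values * out["w1_over_w0"].values,
            rtol=1e-12,
        )

    def test_zero_denominator_flags_wound(self):
        f0 = _fv(np.zeros(12))
        f1 = _fv(np.ones(12))
        out = compute_ratios(features_by_week={0: f0, 1: f1, 2: f1})
        assert not out["w1_over_w0"].valid
        assert out["w2_over_w1"].valid  # 1/1 is fine

    def test_missing_week_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_ratios(areas_by_week={0: 1.0, 1: 2.0})


class TestPCA:
    def test_rank_one_case(self):
        """Two perfectly correlated columns: PC1 explains all variance."""
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = fit_pca(X, feature_names=("a", "b"))
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)
        assert res.explained_variance_fraction[1] == pytest.approx(0.0, abs=1e-12)

    def test_loadings_orthonormal_and_scores_reproduce(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 12)), columns=FEATURE_COLUMNS)
        res = fit_pca(X)
        W = res.loadings.to_numpy()
        np.testing.assert_allclose(W.T @ W, np.eye(2), atol=1e-10)
        Z = (X - res.mean) / res.std
        np.testing.assert_allclose(res.scores, Z.to_numpy() @ W, atol=1e-9)
        assert abs(res.scores.mean(axis=0)).max() < 1e-9

    def test_matches_direct_eigendecomposition(self):
        X = pd.DataFrame(
            [[1.0, 2.0, 0.5], [2.0, 1.5, 0.7], [3.0, 3.5, 0.2], [4.0, 2.5, 0.9]],
            columns=["p", "q", "r"],
        )
        res = fit_pca(X, feature_names=("p", "q", "r"))
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        R = Z.T @ Z / (len(X) - 1)
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1]
        np.testing.assert_allclose(
            res.explained_variance_fraction, vals[order][:2] / vals.sum(), atol=1e-12
        )
        for k in range(2):
            v = vecs[:, order[k]]
            got = res.loadings.to_numpy()[:, k]
            assert np.allclose(got, v, atol=1e-10) or np.allclose(got, -v, atol=1e-10)

    def test_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.decomposition")
        X = pd.DataFrame(rng.normal(size=(30, 12)), columns=FEATURE_COLUMNS)
        res = fit_pca(X)
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        ref = sk.PCA(n_components=2).fit(Z)
        np.testing.assert_allclose(
            res.explained_variance_fraction,
            ref.explained_variance_ratio_,
            atol=1e-10,
        )
        for k in range(2):
            np.testing.assert_allclose(
                np.abs(res.loadings.to_numpy()[:, k]),
                np.abs(ref.components_[k]),
                atol=1e-8,
            )

    def test_sign_convention_inertia_nonnegative(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 12)), columns=FEATURE_COLUMNS)
        res = fit_pca(X)
        assert res.loadings.loc["j_inertia", "PC1"] >= 0
        assert res.loadings.loc["j_inertia", "PC2"] >= 0

    def test_constant_columns_dropped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 12)), columns=FEATURE_COLUMNS)
        X["g_sum_average"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = fit_pca(X)
        assert res.dropped == ["g_sum_average"]
        assert "g_sum_average" not in res.loadings.index

    def test_too_few_observations_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_pca(pd.DataFrame(np.ones((2, 12)), columns=FEATURE_COLUMNS))


class TestNormalityGate:
    def test_matches_r_nortest(self, rng, tmp_path):
        """The AD p-value approximation equals nortest::ad.test's."""
        samples = [
            rng.normal(size=30),
            rng.lognormal(size=50),
            rng.uniform(size=25),
        ]
        for x in samples:
            ours = anderson_darling_pvalue(x)
            script = (
                "suppressMessages(library(nortest));"
                f"x <- c({','.join(repr(float(v)) for v in x)});"
                "cat(sprintf('%.10f', ad.test(x)$p.value))"
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, check=True
            )
            theirs = float(out.stdout.strip())
            assert ours == pytest.approx(theirs, abs=2e-4)

    def test_normal_samples_mostly_pass(self):
        """Seeded H0 simulation: a single normal group is declared
        parametric in about 95% of replicates at alpha = 0.05."""
        n_pass = 0
        reps = 400
        for i in range(reps):
            r = np.random.default_rng(1000 + i)
            gate = normality_gate({"g": r.normal(size=100)})
            n_pass += gate.decision == "parametric"
        assert n_pass / reps >= 0.92

    def test_lognormal_rejected(self):
        r = np.random.default_rng(3)
        gate = normality_gate(
            {"healed": r.normal(size=40), "unhealed": r.lognormal(sigma=1.0, size=72)}
        )
        assert gate.p_values["unhealed"] < 0.05
        assert gate.decision == "nonparametric"

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            normality_gate({"g": [1.0, 2.0]})


class TestKruskalWallis:
    def test_identical_groups(self):
        comp = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert comp.statistic == 0.0 and comp.p_value == 1.0

    def test_hand_derived_h(self):
        """Rank sums R1=6, R2=15 give H = 12/(6*7)*(6^2/3 + 15^2/3) - 21."""
        comp = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert comp.statistic == pytest.approx(27.0 / 7.0, abs=1e-9)
        assert comp.p_value == pytest.approx(sps.chi2.sf(27.0 / 7.0, 1), abs=1e-12)

    def test_all_tied_returns_h0(self):
        comp = kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0])
        assert comp.statistic == 0.0 and comp.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rank_oracle_with_ties(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = r.integers(2, 5), r.integers(2, 5)
        pool = r.integers(0, 4, n1 + n2).astype(float)  # many ties
        g1, g2 = pool[:n1], pool[n2:]
        comp = kruskal_wallis(g1, g2)
        assert comp.statistic == pytest.approx(kruskal_h_oracle(g1, g2), abs=1e-10)

    def test_statistic_correct_over_all_permutations(self):
        """H recomputed by the rank oracle for every assignment of the pooled
        sample into groups matches the implementation (n <= 8)."""
        pooled = np.array([0.3, 1.2, 1.2, 2.5, 3.1, 4.0, 4.0])
        n1 = 3
        for idx in itertools.combinations(range(len(pooled)), n1):
            g1 = pooled[list(idx)]
            g2 = np.delete(pooled, list(idx))
            comp = kruskal_wallis(g1, g2)
            assert comp.statistic == pytest.approx(
                kruskal_h_oracle(g1, g2), abs=1e-10
            )

    def test_descriptives_populated(self):
        comp = kruskal_wallis([1.0, 2.0, 3.0], [4.0, 6.0])
        assert comp.healed_stats.median == 2.0
        assert comp.unhealed_stats.mean == 5.0


class TestAnovaTukey:
    def test_hand_derived_f(self):
        """SSB = 1.5, SSW = 4 with df (1, 4) give F = 1.5."""
        comp = anova_tukey([1, 2, 3], [2, 3, 4])
        assert comp.statistic == pytest.approx(1.5, abs=1e-12)
        assert comp.p_value == pytest.approx(sps.f.sf(1.5, 1, 4), abs=1e-12)

    def test_equal_means_f_zero(self):
        comp = anova_tukey([1.0, 3.0], [0.0, 4.0])
        assert comp.statistic == 0.0

    def test_degenerate_no_variance(self):
        comp = anova_tukey([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(comp.statistic) and np.isnan(comp.p_value)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_f_oracle_and_scipy(self, seed):
        r = np.random.default_rng(seed)
        g1 = r.normal(size=r.integers(3, 9))
        g2 = r.normal(loc=0.5, size=r.integers(3, 9))
        comp = anova_tukey(g1, g2)
        assert comp.statistic == pytest.approx(anova_f_oracle(g1, g2), rel=1e-10)
        f_ref, p_ref = sps.f_oneway(g1, g2)
        assert comp.statistic == pytest.approx(f_ref, rel=1e-10)
        assert comp.p_value == pytest.approx(p_ref, rel=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_tukey_ci_equals_pooled_t(self, seed):
        """With two groups the studentized-range interval collapses to the
        pooled two-sample t interval."""
        r = np.random.default_rng(100 + seed)
        g1 = r.normal(size=7)
        g2 = r.normal(loc=1.0, size=11)
        comp = anova_tukey(g1, g2)
        n = len(g1) + len(g2)
        sp2 = (
            ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        ) / (n - 2)
        half = sps.t.ppf(0.975, n - 2) * np.sqrt(sp2 * (1 / len(g1) + 1 / len(g2)))
        diff = g2.mean() - g1.mean()
        lo, hi = comp.tukey_ci_95
        assert lo == pytest.approx(diff - half, rel=1e-10)
        assert hi == pytest.approx(diff + half, rel=1e-10)
        q = sps.studentized_range.ppf(0.95, 2, n - 2)
        assert q / np.sqrt(2) == pytest.approx(sps.t.ppf(0.975, n - 2), rel=1e-6)

    def test_matches_statsmodels_tukeyhsd(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        g1 = rng.normal(size=9)
        g2 = rng.normal(loc=0.8, size=13)
        comp = anova_tukey(g1, g2)
        data = np.concatenate([g1, g2])
        groups = ["h"] * 9 + ["u"] * 13
        ref = sm.pairwise_tukeyhsd(data, groups, alpha=0.05)
        np.testing.assert_allclose(
            comp.tukey_ci_95, ref.confint[0], atol=1e-8
        )

    def test_small_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            anova_tukey([1.0], [2.0, 3.0])


class TestIntervalSummaryAndPrediction:
    def test_constant_group(self):
        out = interval_summary({"g": [1.0, 1.0, 1.0, 1.0]})["g"]
        assert out.mean == 1.0 and out.ci_half_width == 0.0

    def test_two_points(self):
        out = interval_summary({"g": [0.0, 2.0]})["g"]
        assert out.mean == 1.0 and out.sd == pytest.approx(np.sqrt(2.0))

    def test_closed_form_half_width(self, rng):
        x = rng.normal(size=17)
        out = interval_summary({"g": x})["g"]
        expect = sps.t.ppf(0.975, 16) * x.std(ddof=1) / np.sqrt(17)
        assert out.ci_half_width == pytest.approx(expect, rel=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(DegenerateInputError):
            interval_summary({"g": [1.0]})

    def test_separable_scores_classified_perfectly(self):
        pred = predict_healing(
            [-2.0, -1.0, 1.0, 2.0], [True, True, False, False]
        )
        assert pred.threshold == 0.0
        np.testing.assert_array_equal(
            pred.predicted_healed, [True, True, False, False]
        )

    def test_degenerate_scores_abstain(self):
        pred = predict_healing([1.0, 1.0, 1.0], [True, False, False])
        assert pred.abstained

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            predict_healing([1.0, 2.0], [True, True])
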