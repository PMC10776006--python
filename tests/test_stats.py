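"""Weighted correlation, permutation inference, GLMs and receptor PCA."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dnprf.aggregation import ROITable
from dnprf.stats import (
    SingularDesignError,
    UndefinedCorrelationError,
    WeightedSample,
    component_parameter_scan,
    crossval_glm,
    fit_weighted_glm,
    pca_receptors,
    permutation_test,
    surrogate_pair_test,
    weighted_pearson,
)


class TestWeightedPearson:
    def test_unit_weights_match_classical(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            assert abs(weighted_pearson(x, y) - sps.pearsonr(x, y)[0]) <= 1e-12

    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 5.0])
        w = np.array([0.3, 1.0, 2.0])
        assert np.isclose(weighted_pearson(x, x, w), 1.0)
        assert np.isclose(weighted_pearson(x, -x, w), -1.0)

    def test_hand_computed_example(self):
        r = weighted_pearson([1, 2, 3], [1, 2, 2], [1, 1, 2])
        assert abs(r - 0.870) < 1e-3

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            weighted_pearson([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        c=st.floats(0.1, 10), d=st.floats(-5, 5),
    )
    def test_invariant_under_positive_affine_maps(self, seed, a, b, c, d):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 10))
        w = rng.uniform(0.1, 2.0, 10)
        r = weighted_pearson(x, y, w)
        r2 = weighted_pearson(a * x + b, c * y + d, w)
        assert abs(r - r2) < 1e-9
        assert abs(weighted_pearson(-x, y, w) + r) < 1e-9

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            WeightedSample([1, 2], [1, 2], [1, 1])  # too few
        with pytest.raises(ValueError):
            WeightedSample([1, 2, 3], [1, 2, 3], [-1, 1, 1])  # negative weight


class TestPermutationTest:
    def test_exhaustive_enumeration_small_n(self):
        # only identity and reversal reach |r| = 1 among 3! permutations
        res = permutation_test([1, 2, 3], [1, 2, 3], n_perm=1000, seed=0)
        assert res.exhaustive and res.n_permutations == 6
        assert np.isclose(res.p, 2 / 6)

    def test_exhaustive_matches_manual_enumeration(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 5))
        w = rng.uniform(0.2, 1.5, 5)
        res = permutation_test(x, y, w, n_perm=10**5, seed=0)
        obs = abs(weighted_pearson(x, y, w))
        count = sum(
            abs(weighted_pearson(x[list(p)], y, w)) >= obs - 1e-12
            for p in permutations(range(5))
        )
        assert res.n_permutations == 120
        assert np.isclose(res.p, count / 120)

    def test_sampled_mode_approaches_exhaustive(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 8))
        exact = permutation_test(x, y, n_perm=math.factorial(8), seed=0)
        sampled = permutation_test(x, y, n_perm=20_000, seed=0)
        assert exact.exhaustive and not sampled.exhaustive
        assert abs(sampled.p - exact.p) < 0.02

    def test_zero_exceedance_floored(self):
        # a strong monotone association with many ROIs: no sampled permutation
        # reaches |r_obs|
        n = 40
        x = np.arange(n, dtype=float)
        y = x + 0.01 * np.random.default_rng(0).normal(size=n)
        res = permutation_test(x, y, n_perm=500, seed=1)
        assert res.floored
        assert res.p == 1 / 500
        assert "<" in str(res)

    def test_statistic_equals_weighted_pearson(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 12))
        w = rng.uniform(0.1, 1.0, 12)
        res = permutation_test(x, y, w, n_perm=100, seed=0)
        assert np.isclose(res.statistic, weighted_pearson(x, y, w))


class TestWeightedGLM:
    def test_exact_linear_relation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_weighted_glm(x, 2 * x + 1)
        assert np.allclose(fit.coef, [2.0])
        assert np.isclose(fit.intercept, 1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(SingularDesignError):
            fit_weighted_glm(np.ones(5), np.arange(5.0))

    def test_collinear_pair_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(SingularDesignError):
            fit_weighted_glm(np.column_stack([x, 2 * x + 1]), x)

    def test_two_predictor_limit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = X[:, 0] - X[:, 1] + 1e-9 * rng.normal(size=30)
        fit = fit_weighted_glm(X, y, rng.uniform(0.5, 1.5, 30))
        assert np.allclose(fit.coef, [1.0, -1.0], atol=1e-6)

    def test_weights_matter(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 9.0])
        heavy_tail = fit_weighted_glm(x, y, [1, 1, 1, 10]).coef[0]
        light_tail = fit_weighted_glm(x, y, [10, 10, 10, 1]).coef[0]
        assert heavy_tail > light_tail


class TestCrossvalGLM:
    def test_perfect_positive_prediction(self):
        x = np.arange(6.0)
        w = np.ones(6)
        assert np.isclose(crossval_glm(x, 2 * x, w, x, 2 * x, w), 1.0)

    def test_sign_convention_for_anticorrelated_receptor(self):
        x = np.arange(6.0)
        w = np.ones(6)
        assert np.isclose(crossval_glm(x, -x, w, x, -x, w), -1.0)

    def test_two_receptor_model_returns_plain_wcc(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        y = X @ [1.0, -1.0]
        w = np.ones(15)
        assert np.isclose(crossval_glm(X, y, w, X, y, w), 1.0)


class TestSurrogatePairTest:
    def test_exhaustive_matches_enumeration_four_rois(self):
        rng = np.random.default_rng(4)
        r1, r2 = rng.normal(size=(2, 4))
        y = r1 + r2
        w = np.ones(4)
        res = surrogate_pair_test(r1, r2, y, w, n_perm=10**4, seed=0)
        assert res.n_permutations == 24
        obs = abs(res.observed)
        for name, permuted, fixed in (("r1", r1, r2), ("r2", r2, r1)):
            count = 0
            for p in permutations(range(4)):
                cols = (permuted[list(p)], fixed) if name == "r1" else (fixed, permuted[list(p)])
                fit = fit_weighted_glm(np.column_stack(cols), y, w)
                pred = fit.predict(np.column_stack(cols))
                if abs(weighted_pearson(pred, y, w)) >= obs - 1e-12:
                    count += 1
            assert np.isclose(res.p[name], count / 24)

    def test_strong_planted_effect_is_significant(self):
        rng = np.random.default_rng(7)
        r1, r2 = rng.normal(size=(2, 20))
        y = r1 - r2 + 0.05 * rng.normal(size=20)
        res = surrogate_pair_test(r1, r2, y, n_perm=2000, seed=1)
        assert res.p["r1"] < 0.01 and res.p["r2"] < 0.01


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_one_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        table = pd.DataFrame({"A": base, "B": -3 * base + 7})
        res = pca_receptors(table)
        assert np.isclose(res.variance_ratio[0], 1.0)
        assert res.n_above_threshold == 1

    def test_variance_fractions_sum_to_one_and_scores_uncorrelated(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(20, 6)),
                             columns=list("ABCDEF"))
        res = pca_receptors(table)
        assert abs(res.variance_ratio.sum() - 1.0) < 1e-10
        c = np.corrcoef(res.scores.T)
        assert np.max(np.abs(c - np.eye(6))) < 1e-8

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("ABCD"))
        res = pca_receptors(table)
        for j in range(4):
            col = res.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_constant_column_rejected_when_standardizing(self):
        table = pd.DataFrame({"A": [1.0, 1.0, 1.0, 1.0], "B": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            pca_receptors(table)

    def test_two_latent_factors_dominate(self):
        rng = np.random.default_rng(3)
        f = rng.normal(size=(30, 2))
        load = rng.normal(size=(2, 6))
        table = pd.DataFrame(f @ load + 0.05 * rng.normal(size=(30, 6)),
                             columns=list("ABCDEF"))
        res = pca_receptors(table)
        assert res.variance_ratio[:2].sum() >= 0.9
        assert res.n_above_threshold == 2


class TestComponentParameterScan:
    def _roi_table(self, rng, n=15):
        params = pd.DataFrame({
            "bd": np.linspace(2, 0.1, n) + 0.05 * rng.normal(size=n),
            "d": np.geomspace(3, 0.3, n) * rng.lognormal(0, 0.05, n),
            "weight": rng.uniform(0.2, 0.6, n),
            "n_vertices": np.full(n, 10),
        })
        return params

    def test_component_matching_parameter_profile_has_unit_wcc(self):
        rng = np.random.default_rng(0)
        t = self._roi_table(rng)
        receptors = pd.DataFrame({
            "R1": 2 * t["bd"] + 5, "R2": -t["bd"] + 1,
            "R3": rng.normal(size=len(t)),
        })
        pca = pca_receptors(receptors)
        roi = ROITable(table=pd.concat([t, receptors], axis=1),
                       param_columns=["bd", "d"], receptor_columns=list(receptors))
        scan = component_parameter_scan(pca, roi, n_perm=200, seed=0)
        assert {"component", "parameter", "wcc", "p", "p_floored"} <= set(scan.columns)
        pc1_bd = scan[(scan.component == "PC1") & (scan.parameter == "bd")]
        # PC1 is the bd-driven direction of this receptor set
        top = scan[scan.component == "PC1"].set_index("parameter").wcc.abs()
        assert top.idxmax() == "bd"
        assert abs(pc1_bd.wcc.iloc[0]) > 0.9

    def test_only_supra_threshold_components_scanned(self):
        rng = np.random.default_rng(1)
        t = self._roi_table(rng)
        base = rng.normal(size=len(t))
        receptors = pd.DataFrame({
            "R1": base, "R2": base * 2 + 0.01 * rng.normal(size=len(t)),
        })
        pca = pca_receptors(receptors)
        roi = ROITable(table=pd.concat([t, receptors], axis=1),
                       param_columns=["bd", "d"], receptor_columns=list(receptors))
        scan = component_parameter_scan(pca, roi, n_perm=100, seed=0)
        assert set(scan.component) == {"PC1"}
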