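"""Reliability coefficients, descriptives and group-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icdscreen import irt
from icdscreen import reliability as rel


class TestOmega:
    def test_zero_loadings_give_zero(self):
        assert rel.omega_from_loadings([0.0] * 5) == 0.0

    def test_nine_equal_loadings_closed_form(self):
        # (9*0.9)^2 / ((9*0.9)^2 + 9*(1-0.81))
        assert rel.omega_from_loadings([0.9] * 9) == pytest.approx(
            65.61 / (65.61 + 1.71), abs=1e-12)

    def test_published_idq_loadings_give_high_omega(self, idq_params):
        a, _ = idq_params
        lam = irt.loading_from_discrimination(a)
        omega = rel.omega_from_loadings(lam)
        assert omega == pytest.approx(0.98, abs=0.005)

    @given(st.lists(st.floats(0.0, 0.95), min_size=3, max_size=10),
           st.integers(0, 9), st.floats(0.001, 0.04))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_each_loading(self, lams, pos, bump):
        pos = pos % len(lams)
        raised = list(lams)
        raised[pos] = min(0.999, raised[pos] + bump)
        assert rel.omega_from_loadings(raised) >= rel.omega_from_loadings(lams) - 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rel.omega_from_loadings([])


class TestAlphaAndItemTotal:
    def test_parallel_items_closed_form(self):
        rng = np.random.default_rng(0)
        true = rng.standard_normal(20000)
        x = np.stack([true + rng.standard_normal(20000) for _ in range(4)], axis=1)
        # equal variances v, equal covariances c: alpha = k*c / (v + (k-1)*c)
        v = x.var(axis=0, ddof=1).mean()
        cov = np.cov(x.T)
        c = cov[np.triu_indices(4, 1)].mean()
        assert rel.cronbach_alpha(x) == pytest.approx(4 * c / (v + 3 * c), abs=1e-3)

    def test_duplicated_item_alpha_is_one(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(100)
        assert rel.cronbach_alpha(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30000, 5))
        assert abs(rel.cronbach_alpha(x)) < 0.05

    def test_identical_items_total_correlation_one(self):
        rng = np.random.default_rng(3)
        col = rng.standard_normal(50)
        out = rel.item_total_correlations(np.column_stack([col, col]))
        assert np.allclose(out["total"], 1.0)

    def test_independent_items_attenuation(self):
        # item-vs-total correlation for k independent items tends to sqrt(1/k)
        rng = np.random.default_rng(4)
        k = 6
        x = rng.standard_normal((60000, k))
        out = rel.item_total_correlations(x)
        assert np.allclose(out["total"], np.sqrt(1 / k), atol=0.02)

    def test_zero_variance_item_reported_missing(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 3))
        x[:, 1] = 2.0
        out = rel.item_total_correlations(x)
        assert np.isnan(out["total"][1]) and np.isfinite(out["total"][0])


class TestSkewness:
    def test_symmetric_data_zero(self):
        s, _ = rel.skewness_with_se(np.tile([-1.0, 0.0, 1.0], 50))
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_se_at_published_sample_size(self):
        x = np.random.default_rng(0).standard_normal(2058)
        _, se = rel.skewness_with_se(x)
        assert se == pytest.approx(0.054, abs=5e-4)
        assert round(se, 2) == 0.05

    def test_exponential_skewness_recovered(self):
        x = np.random.default_rng(42).exponential(size=10000)
        s, se = rel.skewness_with_se(x)
        assert abs(s - 2.0) < 3 * max(se, 0.05)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            rel.skewness_with_se(np.ones(10))


class TestTTest:
    def test_identical_groups(self):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)])
        g = ["a"] * 10 + ["b"] * 10
        res = rel.two_group_t(x, g)
        assert res.statistic == pytest.approx(0.0) and res.effect_size == 0.0

    def test_published_sex_difference_from_summaries(self):
        # females n=1069 M=8.03 SD=9.08 vs males n=983 M=7.19 SD=9.40
        res = rel.two_group_t_from_stats(1069, 8.03, 9.08, 983, 7.19, 9.40)
        assert res.df == (2050,)
        assert abs(res.statistic) == pytest.approx(2.05, abs=0.03)
        assert res.effect_size == pytest.approx(0.09, abs=0.01)
        assert res.p == pytest.approx(0.041, abs=0.005)

    def test_shifted_normals_effect_size(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.standard_normal(10000),
                            rng.standard_normal(10000) + 0.5])
        g = np.repeat(["a", "b"], 10000)
        res = rel.two_group_t(x, g)
        assert res.effect_size == pytest.approx(0.5, abs=0.05)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            rel.two_group_t(np.array([1.0, 2.0, 3.0]), ["a", "a", "b"])


TABLE5_IDQ = [(1313, 4.88, 7.41), (402, 10.24, 9.52),
              (170, 17.61, 9.19), (50, 17.98, 10.86)]
TABLE5_IAQ = [(1313, 5.29, 6.77), (402, 11.22, 8.39),
              (170, 17.22, 7.93), (50, 17.10, 9.53)]


class TestAnova:
    def test_equal_means_give_zero_f(self):
        res = rel.oneway_anova_from_stats([(50, 5.0, 2.0), (60, 5.0, 3.0)])
        assert res.statistic == pytest.approx(0.0) and res.effect_size == 0.0

    def test_published_treatment_anova_reconstruction(self):
        res = rel.oneway_anova_from_stats(TABLE5_IDQ)
        assert res.df == (3, 1931)
        assert res.statistic == pytest.approx(174.81, abs=0.5)
        assert res.effect_size == pytest.approx(0.21, abs=0.005)
        # all pairs differ except current (idx 2) vs waiting list (idx 3)
        sig = {(i, j): s for i, j, s in res.posthoc}
        assert sig[(2, 3)] is False
        assert all(s for (i, j), s in sig.items() if (i, j) != (2, 3))

    def test_published_anxiety_effect_size(self):
        res = rel.oneway_anova_from_stats(TABLE5_IAQ)
        assert res.effect_size == pytest.approx(0.24, abs=0.005)

    def test_summary_mode_equals_raw_mode(self):
        rng = np.random.default_rng(11)
        vals = np.concatenate([rng.normal(m, 1, 40) for m in (0, 0.3, 1.0)])
        groups = np.repeat(list("abc"), 40)
        raw = rel.oneway_anova(vals, groups)
        triples = [(40, vals[groups == g].mean(), vals[groups == g].std(ddof=1))
                   for g in "abc"]
        summ = rel.oneway_anova_from_stats(triples)
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-10)
        assert raw.effect_size == pytest.approx(summ.effect_size, rel=1e-10)

    def test_eta_squared_identity(self):
        res = rel.oneway_anova_from_stats(TABLE5_IDQ)
        f, (dfb, dfw) = res.statistic, res.df
        assert res.effect_size == pytest.approx(f * dfb / (f * dfb + dfw), rel=1e-12)

    @given(st.lists(
        st.tuples(st.integers(5, 80), st.floats(-3, 3), st.floats(0.5, 3)),
        min_size=3, max_size=5))
    @settings(derandomize=True, max_examples=60)
    def test_scheffe_never_more_liberal_than_unadjusted_t(self, triples):
        from scipy import stats as ss
        res = rel.oneway_anova_from_stats(triples)
        ns = [t[0] for t in triples]
        means = [t[1] for t in triples]
        dfw = res.df[1]
        mse = None
        ssw = sum((n - 1) * s**2 for n, _, s in triples)
        mse = ssw / dfw
        for i, j, sig in res.posthoc:
            t_stat = abs(means[i] - means[j]) / np.sqrt(
                mse * (1 / ns[i] + 1 / ns[j]))
            unadj_sig = 2 * ss.t.sf(t_stat, dfw) < 0.05
            if sig:
                assert unadj_sig


class TestChiSquareAndCorrelation:
    def test_proportional_table_is_zero(self):
        assert rel.chi_square_association([[10, 20], [20, 40]]).statistic == \
            pytest.approx(0.0)

    def test_hand_computed_oracle(self):
        # [[10,20],[20,10]]: all expected counts are 15
        expected_chi2 = 4 * (5**2) / 15
        res = rel.chi_square_association([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(expected_chi2, rel=1e-12)
        assert res.df == (1,)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            rel.chi_square_association([[0, 0], [5, 5]])

    def test_pearson_perfect(self):
        x = np.arange(10.0)
        assert rel.pearson_r(x, x)[0] == pytest.approx(1.0)
        assert rel.pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_bivariate_normal(self):
        rng = np.random.default_rng(12)
        z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=50000)
        r, p = rel.pearson_r(z[:, 0], z[:, 1])
        assert r == pytest.approx(0.9, abs=0.005)
        assert p < 1e-10

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            rel.pearson_r(np.ones(10), np.arange(10.0))
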