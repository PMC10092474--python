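"""Normal-ogive IRT: tetrachorics, MML estimation, conversions, information,
fit indices."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr

from icdscreen import irt
from tests.conftest import simulate_binary


# --- independent oracles -----------------------------------------------------

def bvn_cdf_grid(x, y, r_grid, n_nodes=96):
    """P(Z1<=x, Z2<=y; r) for a grid of correlations, by Gauss-Legendre
    integration of phi(t)*Phi((y-rt)/sqrt(1-r^2)) over t in (-8, x]."""
    t, w = np.polynomial.legendre.leggauss(n_nodes)
    lo = -8.0
    t = (x - lo) / 2 * t + (x + lo) / 2
    w = (x - lo) / 2 * w
    r = np.asarray(r_grid)[:, None]
    inner = ndtr((y - r * t[None, :]) / np.sqrt(1 - r**2))
    return (w[None, :] * stats.norm.pdf(t)[None, :] * inner).sum(axis=1)


def tetrachoric_grid_mle(table):
    """Brute-force grid MLE over r of the multinomial likelihood with
    thresholds fixed at the margins."""
    t = np.asarray(table, dtype=float)
    if np.any(t == 0):
        t = t + 0.5
    n = t.sum()
    tx = stats.norm.ppf(t[0].sum() / n)
    ty = stats.norm.ppf(t[:, 0].sum() / n)

    def loglik(r_grid):
        p00 = bvn_cdf_grid(tx, ty, r_grid)
        p0x = ndtr(tx)
        p0y = ndtr(ty)
        p01 = p0x - p00
        p10 = p0y - p00
        p11 = 1 - p0x - p0y + p00
        probs = np.clip(np.stack([p00, p01, p10, p11]), 1e-12, 1)
        return (t.ravel()[:, None] * np.log(probs)).sum(axis=0)

    coarse = np.linspace(-0.995, 0.995, 399)
    r0 = coarse[np.argmax(loglik(coarse))]
    fine = np.linspace(max(-0.9999, r0 - 0.01), min(0.9999, r0 + 0.01), 801)
    return fine[np.argmax(loglik(fine))]


# --- closed forms and conversions -------------------------------------------

class TestMarginalEndorsement:
    @pytest.mark.parametrize(
        "a, b, expected_pct",
        [(2.864, 1.190, 13.1), (1.571, 1.077, 18.2)],
    )
    def test_matches_published_endorsement(self, a, b, expected_pct):
        assert 100 * irt.marginal_endorsement(a, b) == pytest.approx(
            expected_pct, abs=0.3)

    @pytest.mark.parametrize("a", [0.3, 1.0, 2.5])
    def test_zero_difficulty_gives_half(self, a):
        assert irt.marginal_endorsement(a, 0.0) == pytest.approx(0.5)


class TestParamConversions:
    def test_unit_discrimination_loading(self):
        assert irt.loading_from_discrimination(1.0) == pytest.approx(
            1 / np.sqrt(2), abs=1e-6)

    def test_round_trip_identity(self):
        a = 2.864
        lam = irt.loading_from_discrimination(a)
        assert irt.discrimination_from_loading(lam) == pytest.approx(a, abs=1e-10)
        b = 1.19
        tau = irt.threshold_from_params(a, b)
        assert irt.difficulty_from_threshold(a, tau) == pytest.approx(b, abs=1e-10)

    def test_threshold_consistent_with_endorsement(self):
        # IAQ item 1: Phi(-tau) should reproduce its published endorsement rate
        tau = irt.threshold_from_params(3.369, 1.044)
        assert 100 * ndtr(-tau) == pytest.approx(15.8, abs=0.3)

    def test_degenerate_loading_raises(self):
        with pytest.raises(ValueError):
            irt.discrimination_from_loading(1.0)


class TestTetrachoric:
    def test_independent_table_is_zero(self):
        assert irt.tetrachoric_correlation([[25, 25], [25, 25]]) == pytest.approx(
            0.0, abs=1e-8)

    def test_symmetric_half_margins_closed_form(self):
        # margins 50/50 put both thresholds at 0, where
        # P(00) = 1/4 + arcsin(r)/(2*pi); with P(00)=0.4, r = sin(0.3*pi)
        r = irt.tetrachoric_correlation([[40, 10], [10, 40]])
        assert r == pytest.approx(np.sin(0.3 * np.pi), abs=1e-6)

    def test_against_grid_mle(self):
        table = [[30, 12], [8, 50]]
        assert irt.tetrachoric_correlation(table) == pytest.approx(
            tetrachoric_grid_mle(table), abs=1e-3)

    def test_random_tables_match_grid_mle(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = rng.integers(200, 800)
            r_true = rng.uniform(-0.85, 0.85)
            tx, ty = rng.uniform(-1, 1, size=2)
            z = rng.multivariate_normal([0, 0], [[1, r_true], [r_true, 1]], size=n)
            x, y = (z[:, 0] > tx).astype(int), (z[:, 1] > ty).astype(int)
            tab = np.array([[np.sum((x == i) & (y == j)) for j in (0, 1)]
                            for i in (0, 1)])
            if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
                continue
            est = irt.tetrachoric_correlation(tab)
            assert est == pytest.approx(tetrachoric_grid_mle(tab), abs=1e-3)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            irt.tetrachoric_correlation([[0, 0], [10, 10]])

    def test_zero_cell_warns_and_corrects(self):
        with pytest.warns(UserWarning, match="continuity"):
            r = irt.tetrachoric_correlation([[40, 0], [10, 50]])
        assert -1 < r < 1


class TestEstimation:
    def test_2pl_recovery_and_em_monotone(self, idq_params):
        a, b = idq_params
        x = simulate_binary(a, b, 4000, seed=11)
        fit = irt.fit_2pl(x, compute_se=True)
        assert fit.converged
        assert np.abs(fit.a - a).max() < 0.6   # single-cohort sampling noise
        assert np.abs(fit.b - b).max() < 0.2
        d = np.diff(fit.loglik_path)
        assert (d >= -1e-6).all()          # EM + polish never decrease loglik
        assert all(p.se_a is not None and p.se_a > 0 for p in fit.params)

    def test_1pl_recovers_common_discrimination(self, idq_params):
        _, b = idq_params
        a_common = 2.0
        x = simulate_binary(np.full(9, a_common), b, 5000, seed=3)
        fit = irt.fit_1pl(x)
        assert fit.params[0].a == pytest.approx(a_common, abs=0.2)
        assert fit.n_params == 10

    def test_nesting_loglik_order(self, iaq_params):
        a, b = iaq_params
        x = simulate_binary(a, b, 1500, seed=5)
        f2 = irt.fit_2pl(x, compute_se=False)
        f1 = irt.fit_1pl(x, compute_se=False)
        assert f1.loglik <= f2.loglik + 1e-6
        chi2, df, p = irt.lr_test(f1, f2)
        assert chi2 >= 0 and df == 7 and 0 <= p <= 1

    def test_single_item_is_unidentified(self):
        with pytest.raises(ValueError):
            irt.fit_2pl(np.array([[0], [1], [1]]))

    def test_zero_variance_item_excluded_with_warning(self, idq_params):
        a, b = idq_params
        x = simulate_binary(a[:3], b[:3], 500, seed=2)
        x[:, 1] = 0
        with pytest.warns(UserWarning, match="zero variance"):
            fit = irt.fit_2pl(x, compute_se=False)
        assert len(fit.params) == 2

    def test_perfectly_correlated_items_hit_discrimination_bound(self):
        rng = np.random.default_rng(0)
        col = (rng.random(800) < 0.4).astype(int)
        x = np.column_stack([col, col])
        with pytest.warns(UserWarning):
            fit = irt.fit_2pl(x, compute_se=False)
        assert fit.flagged_items  # capped at the bound

    def test_lr_test_identical_fits(self, iaq_params):
        a, b = iaq_params
        x = simulate_binary(a, b, 800, seed=9)
        f2 = irt.fit_2pl(x, compute_se=False)
        f2_restr = irt.FitResult(
            model="1PL", params=f2.params, loglik=f2.loglik,
            n_params=f2.n_params - 7, n_obs=f2.n_obs, converged=True,
            n_iter=1, loglik_path=f2.loglik_path)
        chi2, df, p = irt.lr_test(f2_restr, f2)
        assert chi2 == 0 and p == 1.0

    def test_lr_test_rejects_non_nested(self, iaq_params):
        a, b = iaq_params
        x = simulate_binary(a, b, 500, seed=1)
        f2 = irt.fit_2pl(x, compute_se=False)
        with pytest.raises(ValueError):
            irt.lr_test(f2, f2)

    def test_self_consistency_endorsement_rates(self, iaq_params):
        # feeding estimates back through the closed form reproduces the
        # observed endorsement rates
        a, b = iaq_params
        x = simulate_binary(a, b, 8000, seed=21)
        fit = irt.fit_2pl(x, compute_se=False)
        implied = np.array([irt.marginal_endorsement(p.a, p.b) for p in fit.params])
        assert np.abs(implied - x.mean(axis=0)).max() < 0.01


class TestInformation:
    def test_icc_half_at_difficulty(self):
        params = [irt.ItemParams2PL(a=2.5, b=1.1)]
        out = irt.information_curves(params, [1.1])
        assert out["icc"][0, 0] == pytest.approx(0.5)

    def test_information_closed_form_at_peak(self):
        params = [irt.ItemParams2PL(a=1.0, b=0.0)]
        out = irt.information_curves(params, [0.0])
        expected = stats.norm.pdf(0) ** 2 / 0.25
        assert out["item_info"][0, 0] == pytest.approx(expected, abs=1e-9)

    def test_total_information_peaks_above_mean_for_published_idq(self, idq_params):
        a, b = idq_params
        params = [irt.ItemParams2PL(ai, bi) for ai, bi in zip(a, b)]
        grid = np.linspace(-4, 4, 801)
        out = irt.information_curves(params, grid)
        peak = grid[np.argmax(out["total_info"])]
        assert 1.0 <= peak <= 1.4
        assert (out["total_info"] >= 0).all()
        assert np.isfinite(np.trapezoid(out["total_info"], grid))

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            irt.information_curves([irt.ItemParams2PL(1, 0)], [])


class TestFitIndices:
    def test_perfect_fit(self):
        r = np.array([[1, 0.5, 0.4], [0.5, 1, 0.45], [0.4, 0.45, 1.0]])
        fi = irt.fit_indices(r, r, n=500, df=2)
        assert fi.srmr == 0 and fi.rmsea == 0 and fi.cfi == 1.0

    def test_uniform_perturbation_gives_srmr(self, idq_params):
        a, _ = idq_params
        lam = irt.loading_from_discrimination(a)
        implied = np.outer(lam, lam)
        np.fill_diagonal(implied, 1.0)
        observed = implied + 0.01
        np.fill_diagonal(observed, 1.0)
        fi = irt.fit_indices(observed, implied, n=2058,
                             df=irt.model_df(9, "2PL"))
        assert fi.srmr == pytest.approx(0.01, abs=1e-12)

    def test_nonpositive_df_disables_rmsea_tli(self):
        r = np.eye(3)
        fi = irt.fit_indices(r, r, n=100, df=0)
        assert fi.rmsea is None and fi.tli is None

    def test_model_df_matches_published_layout(self):
        assert irt.model_df(9, "2PL") == 27
        assert irt.model_df(9, "1PL") == 35
        assert irt.model_df(8, "2PL") == 20
        assert irt.model_df(8, "1PL") == 27
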