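"""Dispersion estimation: Cox-Reid MLEs, trend, prior width, MAP, outliers."""

import numpy as np
import pytest
from scipy.special import polygamma

from nbshrink.dispersion import (
    classify_dispersion_outliers,
    cr_adjusted_loglik,
    estimate_dispersions,
    estimate_prior_variance,
    fit_dispersion_trend,
    genewise_dispersion_mle,
    initial_dispersion_mom,
    map_dispersion,
    MOM_FLOOR,
)
from nbshrink.glm import nb_log_pmf


def nb_counts(rng, mu, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestMomDispersion:
    def test_constant_counts_hit_floor(self):
        X = np.ones((3, 1))
        a = initial_dispersion_mom([10, 10, 10], X, np.ones(3))
        assert a[0] == MOM_FLOOR

    def test_overdispersed_row_hand_value(self):
        # mean 10, sample variance 49 -> (49 - 10)/100 = 0.39
        row = np.array([3, 10, 17])
        a = initial_dispersion_mom(row, np.ones((3, 1)), np.ones(3))
        assert a[0] == pytest.approx(0.39)

    def test_two_constant_groups_hit_floor(self, two_group_info):
        info = two_group_info(6)
        X = np.column_stack([np.ones(6), (info.condition == "B").to_numpy(float)])
        a = initial_dispersion_mom([5, 5, 5, 9, 9, 9], X, np.ones(6))
        assert a[0] == MOM_FLOOR


class TestCoxReidLoglik:
    def test_single_sample_adjustment_is_half_log_weight(self):
        # for m=1, intercept design: adjustment = -0.5*log(w11)
        k, mu, alpha = 7, 5.0, 0.3
        w11 = 1.0 / (1.0 / mu + alpha)
        expected = nb_log_pmf(k, mu, alpha) - 0.5 * np.log(w11)
        got = cr_adjusted_loglik(alpha, [[k]], [[mu]], np.ones((1, 1)))
        assert got[0] == pytest.approx(expected, rel=1e-12)

    def test_adjustment_term_decreases_in_alpha(self):
        mu = np.full((1, 5), 20.0)
        X = np.ones((5, 1))
        counts = np.array([[18, 22, 19, 21, 20]])
        adj = []
        for alpha in (0.01, 0.1, 1.0):
            w = 1.0 / (1.0 / mu + alpha)
            M = X.T @ np.diag(w[0]) @ X
            adj.append(-0.5 * np.log(np.linalg.det(M)))
        assert adj[0] < adj[1] < adj[2]

    def test_adjustment_vanishes_for_large_samples(self, rng):
        # m=200: adjusted and unadjusted MLEs agree within 5%
        m, true_alpha, mu = 200, 0.2, 100.0
        counts = nb_counts(rng, mu, true_alpha, (50, m)).astype(float)
        X = np.ones((m, 1))
        mu0 = np.broadcast_to(counts.mean(axis=1, keepdims=True), counts.shape)
        grid = np.exp(np.linspace(np.log(0.05), np.log(1.0), 600))
        ll_adj = np.stack([cr_adjusted_loglik(a, counts, mu0, X) for a in grid])
        ll_un = np.stack([nb_log_pmf(counts, mu0, a).sum(axis=1) for a in grid])
        ratio = grid[np.argmax(ll_adj, 0)] / grid[np.argmax(ll_un, 0)]
        assert np.median(np.abs(np.log(ratio))) < np.log(1.05)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cr_adjusted_loglik(-1.0, [[1]], [[1.0]], np.ones((1, 1)))


class TestGenewiseMLE:
    def test_poisson_rows_concentrate_at_lower_bound(self, rng):
        # no overdispersion: the typical estimate collapses to (near) the
        # lower optimization bound; individual rows can fluctuate upward
        counts = rng.poisson(50, size=(60, 20))
        alpha, at_bound, _ = genewise_dispersion_mle(counts, np.ones((20, 1)), np.ones(20))
        assert np.median(alpha) < 1e-3
        assert np.mean(at_bound | (alpha < 1e-4)) > 0.5

    def test_monte_carlo_recovery(self, rng):
        # 500 replicate genes, true alpha 0.2, mu 100, m=50:
        # the median estimate recovers the truth within 10%
        m = 50
        counts = nb_counts(rng, 100.0, 0.2, (500, m))
        alpha, _, _ = genewise_dispersion_mle(counts, np.ones((m, 1)), np.ones(m))
        assert np.median(alpha) == pytest.approx(0.2, rel=0.10)

    def test_matches_dense_grid_search(self, rng, two_group_info):
        # oracle: dense grid over log alpha in [-18, 6] at 1e-3 resolution
        info = two_group_info(8)
        X = np.column_stack([np.ones(8), (info.condition == "B").to_numpy(float)])
        n = 20
        counts = nb_counts(rng, rng.uniform(10, 300, (n, 1)), 0.3, (n, 8))
        alpha, _, mu0 = genewise_dispersion_mle(counts, X, np.ones(8))

        log_grid = np.arange(-18.0, 6.0, 1e-3)
        best_val = np.full(n, -np.inf)
        best_arg = np.zeros(n)
        for chunk in np.array_split(log_grid, 50):
            vals = np.stack(
                [cr_adjusted_loglik(np.exp(g), counts, mu0, X) for g in chunk]
            )
            idx = vals.argmax(axis=0)
            better = vals.max(axis=0) > best_val
            best_val = np.maximum(best_val, vals.max(axis=0))
            best_arg = np.where(better, chunk[idx], best_arg)
        np.testing.assert_allclose(np.log(alpha), best_arg, atol=5e-3)


class TestDispersionTrend:
    def test_noiseless_recovery(self):
        bar_mu = np.geomspace(1, 1e4, 300)
        alpha = 3.0 / bar_mu + 0.05
        a1, alpha0, tv = fit_dispersion_trend(alpha, bar_mu)
        assert a1 == pytest.approx(3.0, rel=1e-3)
        assert alpha0 == pytest.approx(0.05, rel=1e-3)
        np.testing.assert_allclose(tv, alpha, rtol=1e-3)

    def test_flat_dispersion_recovery(self):
        bar_mu = np.geomspace(1, 1e4, 300)
        alpha = np.full(300, 0.1)
        a1, alpha0, _ = fit_dispersion_trend(alpha, bar_mu)
        assert alpha0 == pytest.approx(0.1, abs=5e-3)
        assert a1 / np.median(bar_mu) < 0.01  # negligible 1/mu component

    def test_extreme_outlier_excluded_by_ratio_rule(self, rng):
        bar_mu = np.geomspace(1, 1e4, 200)
        alpha = (3.0 / bar_mu + 0.05) * rng.lognormal(0, 0.2, 200)
        a1_ref, alpha0_ref, _ = fit_dispersion_trend(alpha, bar_mu)
        spiked = alpha.copy()
        spiked[100] = 1000.0 * (3.0 / bar_mu[100] + 0.05)
        a1, alpha0, _ = fit_dispersion_trend(spiked, bar_mu)
        assert a1 == pytest.approx(a1_ref, rel=0.01)
        assert alpha0 == pytest.approx(alpha0_ref, rel=0.01)

    def test_degenerate_input_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="flat median trend"):
            a1, alpha0, tv = fit_dispersion_trend(np.array([0.2]), np.array([10.0]))
        assert a1 == 0.0 and alpha0 == pytest.approx(0.2)


class TestPriorVariance:
    def test_trigamma_subtraction(self):
        # sigma_d^2 = s_lr^2 - psi1((m-p)/2); construct residuals whose
        # scaled MAD is known by using a tight grid of normal quantiles
        from scipy import stats as ss

        target_s2 = 2.0
        u = (np.arange(1, 2001) - 0.5) / 2000
        logres = ss.norm.ppf(u) * np.sqrt(target_s2)
        genewise = 0.1 * np.exp(logres)
        trend = np.full_like(genewise, 0.1)
        sd2, s_lr = estimate_prior_variance(genewise, trend, m=12, p=2)
        assert s_lr**2 == pytest.approx(2.0, rel=5e-3)
        assert sd2 == pytest.approx(2.0 - polygamma(1, 5), rel=6e-3)
        assert polygamma(1, 5) == pytest.approx(0.221323, abs=1e-6)

    def test_floor_at_quarter(self):
        # s_lr^2 = 0.3 < psi1(2) = 0.644934 -> floored at exactly 0.25
        from scipy import stats as ss

        u = (np.arange(1, 501) - 0.5) / 500
        logres = ss.norm.ppf(u) * np.sqrt(0.3)
        genewise = 0.1 * np.exp(logres)
        trend = np.full_like(genewise, 0.1)
        sd2, s_lr = estimate_prior_variance(genewise, trend, m=6, p=2)
        assert polygamma(1, 2) == pytest.approx(0.644934, abs=1e-6)
        assert s_lr**2 < polygamma(1, 2)
        assert sd2 == 0.25

    @pytest.mark.parametrize("f", [4, 10, 40])
    def test_trigamma_is_variance_of_log_chi2(self, rng, f):
        # Monte-Carlo check of Var(log X) = psi1(f/2) for X ~ chi2_f
        n = 40_000
        x = np.log(rng.chisquare(f, size=n))
        v = x.var(ddof=1)
        m4 = np.mean((x - x.mean()) ** 4)
        se = np.sqrt((m4 - v**2) / n)
        assert abs(v - polygamma(1, f / 2)) < 3 * se

    def test_low_df_uses_kl_matching(self, rng):
        # m - p <= 3: the prior width is picked from the simulation grid
        # and recovers a planted sigma_d^2 = 1.0 within the grid spacing
        df = 2
        true_sd2 = 1.0
        logres = (
            np.log(rng.chisquare(df, 20000)) - np.log(df)
            + rng.normal(0, np.sqrt(true_sd2), 20000)
        )
        genewise = 0.1 * np.exp(logres)
        trend = np.full_like(genewise, 0.1)
        sd2, _ = estimate_prior_variance(genewise, trend, m=4, p=2)
        grid = 0.25 * 1.25 ** np.arange(25)
        assert sd2 in grid
        assert 0.6 < sd2 < 1.6


class TestMapDispersion:
    def _fixture(self, rng, n=30, m=8):
        counts = nb_counts(rng, 50.0, 0.3, (n, m))
        X = np.ones((m, 1))
        alpha_gw, _, mu0 = genewise_dispersion_mle(counts, X, np.ones(m))
        return counts, X, alpha_gw, mu0

    def test_flat_prior_limit_is_mle(self, rng):
        counts, X, alpha_gw, mu0 = self._fixture(rng)
        trend = np.full(len(counts), 0.1)
        a_map, _ = map_dispersion(counts, mu0, X, trend, prior_var=1e8)
        np.testing.assert_allclose(np.log(a_map), np.log(alpha_gw), atol=0.02)

    def test_point_prior_limit_is_trend(self, rng):
        counts, X, _, mu0 = self._fixture(rng)
        trend = np.full(len(counts), 0.17)
        a_map, _ = map_dispersion(counts, mu0, X, trend, prior_var=1e-7)
        np.testing.assert_allclose(a_map, 0.17, rtol=0.01)

    def test_map_between_genewise_and_trend_when_unimodal(self, rng):
        counts, X, alpha_gw, mu0 = self._fixture(rng, n=50)
        trend = np.full(50, 0.1)
        a_map, _ = map_dispersion(counts, mu0, X, trend, prior_var=0.5)
        lo = np.minimum(np.log(alpha_gw), np.log(trend))
        hi = np.maximum(np.log(alpha_gw), np.log(trend))
        # verify unimodality of the posterior on a coarse grid first
        grid = np.linspace(np.log(1e-6), np.log(10), 60)
        for i in range(50):
            vals = [
                cr_adjusted_loglik(np.exp(g), counts[i : i + 1], mu0[i : i + 1], X)[0]
                - (g - np.log(trend[i])) ** 2 / 1.0
                for g in grid
            ]
            d = np.sign(np.diff(vals))
            unimodal = np.sum((d[:-1] > 0) & (d[1:] < 0)) <= 1
            if unimodal:
                assert lo[i] - 1e-6 <= np.log(a_map[i]) <= hi[i] + 1e-6


class TestOutliersAndShrinkage:
    def test_one_sided_two_sd_rule(self):
        trend = np.full(3, 0.1)
        s_lr = 0.4
        genewise = 0.1 * np.exp(np.array([2.1, 1.9, -5.0]) * s_lr)
        flags = classify_dispersion_outliers(genewise, trend, s_lr)
        np.testing.assert_array_equal(flags, [True, False, False])

    def test_outlier_final_equals_genewise_bitwise(self, rng, two_group_info):
        info = two_group_info(6)
        X = np.column_stack([np.ones(6), (info.condition == "B").to_numpy(float)])
        counts = nb_counts(rng, 100.0, 0.1, (150, 6))
        # plant a wildly overdispersed gene
        counts[0] = [1, 900, 5, 800, 2, 1000]
        model = estimate_dispersions(counts, X, np.ones(6))
        assert model.outlier_flags.any()
        for i in np.flatnonzero(model.outlier_flags):
            assert model.final[i] == model.genewise[i]
        ok = ~model.outlier_flags
        np.testing.assert_array_equal(model.final[ok], model.map[ok])

    def test_shrinkage_weakens_with_sample_size(self, rng):
        # |log MAP - log genewise| shrinks as m grows (6 -> 20)
        deltas = {}
        for m in (6, 20):
            counts = nb_counts(rng, 100.0, 0.2 * rng.lognormal(0, 0.5, (200, 1)), (200, m))
            X = np.ones((m, 1))
            alpha_gw, _, mu0 = genewise_dispersion_mle(counts, X, np.ones(m))
            trend = np.full(200, 0.2)
            a_map, _ = map_dispersion(counts, mu0, X, trend, prior_var=0.25)
            deltas[m] = np.mean(np.abs(np.log(a_map) - np.log(alpha_gw)))
        assert deltas[20] < deltas[6]

    def test_map_rmse_beats_genewise_at_small_m(self, rng, two_group_info):
        # the point of shrinkage: lower log-space RMSE against the truth
        m = 6
        info = two_group_info(m)
        X = np.column_stack([np.ones(m), (info.condition == "B").to_numpy(float)])
        true_alpha = 0.1 * rng.lognormal(0, 0.5, 400)
        counts = nb_counts(rng, 150.0, true_alpha[:, None], (400, m))
        model = estimate_dispersions(counts, X, np.ones(m))
        ok = np.isfinite(model.map) & np.isfinite(model.genewise)
        rmse_map = np.sqrt(np.mean((np.log(model.map[ok]) - np.log(true_alpha[ok])) ** 2))
        rmse_gw = np.sqrt(
            np.mean((np.log(model.genewise[ok]) - np.log(true_alpha[ok])) ** 2)
        )
        assert rmse_map < rmse_gw
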