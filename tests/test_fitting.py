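"""Slope-distribution and power-law fits, bands and goodness of fit."""

import numpy as np
import pytest

from htarisk.fitting import (
    bootstrap_slope_interval,
    fatality_ratio,
    fit_improved_normal,
    fit_improved_normal_density,
    fit_normal,
    fit_powerlaw_linear,
    fit_powerlaw_loglog,
    fn_band,
    goodness_of_fit,
    goodness_of_fit_histogram,
    improved_normal_density,
    normal_density,
    select_model,
)
from htarisk.fncurve import FatalityGroup, cumulative_frequency, series_from_table
from htarisk.synthetic import generate_deaths


def exact_powerlaw_series(a=2.0, C=1.0, n_points=6):
    """A series whose printed F lie exactly on F = C*N^(-a)."""
    N = np.arange(1, n_points + 1)
    return series_from_table(zip(N, np.ones(n_points, dtype=int))), None


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        r2, rmse = goodness_of_fit([1, 2, 3, 4], [1, 2, 3, 4])
        assert (r2, rmse) == (1.0, 0.0)

    def test_mean_predictor_gives_zero_r2(self):
        obs = [1.0, 2.0, 3.0, 6.0]
        r2, _ = goodness_of_fit(obs, [3.0] * 4, n_params=1)
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_case(self):
        obs = np.array([1.0, 2.0, 4.0, 5.0])
        pred = np.array([1.5, 2.5, 3.5, 4.5])
        sse = 0.25 + 0.25 + 0.25 + 0.25
        sst = ((obs - 3.0) ** 2).sum()
        r2, rmse = goodness_of_fit(obs, pred, n_params=2)
        assert r2 == pytest.approx(1 - sse / sst)
        assert rmse == pytest.approx(np.sqrt(sse / 2))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit([2.0, 2.0, 2.0], [2.0, 2.1, 1.9])


class TestFitNormal:
    def test_moments_match_textbook_formulas(self, china_slopes):
        fit = fit_normal(china_slopes)
        assert fit.mu == pytest.approx(np.mean(china_slopes), abs=1e-12)
        assert fit.sigma == pytest.approx(np.std(china_slopes, ddof=1), abs=1e-12)
        lo, hi = fit.interval_95
        assert lo == pytest.approx(fit.mu - 1.96 * fit.sigma, abs=1e-12)
        assert hi == pytest.approx(fit.mu + 1.96 * fit.sigma, abs=1e-12)

    def test_constant_slopes_degenerate(self):
        fit = fit_normal([-1.0, -1.0, -1.0])
        assert (fit.mu, fit.sigma) == (-1.0, 0.0)

    def test_needs_two_slopes(self):
        with pytest.raises(ValueError):
            fit_normal([-1.2])


class TestFitImprovedNormal:
    def test_self_consistency_exact_recovery(self):
        # densities generated from a known quadruple refit to 1e-6
        B, D, mu, sigma = 0.03, 0.7, -1.37, 0.12
        centers = np.linspace(-1.6, -1.1, 8)
        density = improved_normal_density(centers, B, D, mu, sigma)
        est = fit_improved_normal_density(centers, density, p0=[0.0, 0.5, -1.3, 0.1])
        assert np.allclose(est, [B, D, mu, sigma], atol=1e-6)

    def test_reproduces_published_parameters_with_five_bins(self, china_slopes):
        fit = fit_improved_normal(china_slopes, bins=5)
        assert fit.mu == pytest.approx(-1.3701, abs=0.02)
        assert fit.sigma == pytest.approx(0.1182, abs=0.02)
        assert fit.B is not None and fit.D is not None

    def test_symmetric_data_centres_near_mode(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(-1.3, 0.05, size=400)
        fit = fit_improved_normal(sample, bins=10)
        assert fit.mu == pytest.approx(-1.3, abs=0.02)

    def test_needs_four_slopes(self):
        with pytest.raises(ValueError):
            fit_improved_normal([-1.0, -1.1, -1.2])


class TestHistogramGoodness:
    def test_exact_density_scores_one(self):
        rng = np.random.default_rng(1)
        sample = rng.normal(0, 1, 200)
        centers_density = np.histogram(sample, bins=6, density=True)
        centers = 0.5 * (centers_density[1][:-1] + centers_density[1][1:])
        exact = dict(zip(centers, centers_density[0]))
        r2, rmse = goodness_of_fit_histogram(sample, lambda x: np.array([exact[v] for v in x]), bins=6)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_binning_changes_the_metric(self, china_slopes):
        mu, sigma = np.mean(china_slopes), np.std(china_slopes, ddof=1)
        dens = lambda x: normal_density(x, mu, sigma)
        r2_a, _ = goodness_of_fit_histogram(china_slopes, dens, bins=6)
        r2_b, _ = goodness_of_fit_histogram(china_slopes, dens, bins=12)
        assert r2_a != pytest.approx(r2_b)


class TestPowerLawFits:
    def test_exact_line_loglog(self):
        N = np.array([1, 2, 4, 8, 16])
        F = 1.0 * N ** (-2.0)
        from htarisk.fncurve import FNSeries

        series = FNSeries(N, np.ones(5, int), F)
        fit = fit_powerlaw_loglog(series)
        assert fit.a_hat == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        lo, hi = fit.a_interval_95
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_exact_curve_linear(self):
        from htarisk.fncurve import FNSeries

        N = np.array([1, 2, 3, 5, 9])
        series = FNSeries(N, np.ones(5, int), 0.5 * N ** (-1.0))
        fit = fit_powerlaw_linear(series)
        assert fit.a_hat == pytest.approx(1.0, abs=1e-8)
        assert fit.C_hat == pytest.approx(0.5, abs=1e-8)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    def test_china_loglog_slope(self, china_series):
        fit = fit_powerlaw_loglog(china_series)
        assert fit.a_hat == pytest.approx(1.357, abs=5e-4)

    def test_china_linear_intervals_match_published_band(self, china_series):
        fit = fit_powerlaw_linear(china_series)
        assert fit.a_interval_95[0] == pytest.approx(1.229, abs=1e-3)
        assert fit.a_interval_95[1] == pytest.approx(1.378, abs=1e-3)
        assert fit.C_interval_95[0] == pytest.approx(0.9757, abs=1e-3)
        assert fit.C_interval_95[1] == pytest.approx(1.057, abs=1e-3)

    def test_degenerate_inputs_rejected(self, china_series):
        from htarisk.fncurve import FNSeries

        with pytest.raises(ValueError):
            fit_powerlaw_loglog(FNSeries(np.array([2]), np.array([1]), np.array([1.0])))


class TestModelSelection:
    def test_china_ranking_power_law_first(self, china_series, china_slopes):
        fits = [
            fit_normal(china_slopes, bins="sturges"),
            fit_improved_normal(china_slopes, bins="sturges"),
            fit_powerlaw_linear(china_series),
        ]
        ranked = select_model(fits)
        assert ranked[0] is fits[2]

    def test_rank_matches_sort_oracle(self):
        class Fit:
            def __init__(self, r2, rmse):
                self.r2, self.rmse = r2, rmse

        fits = [Fit(0.5, 0.2), Fit(0.9, 0.3), Fit(0.9, 0.1), Fit(0.2, 0.9)]
        ranked = select_model(fits)
        assert [(f.r2, f.rmse) for f in ranked] == [(0.9, 0.1), (0.9, 0.3), (0.5, 0.2), (0.2, 0.9)]

    def test_ties_stable_in_input_order(self):
        class Fit:
            def __init__(self, tag):
                self.r2, self.rmse, self.tag = 0.8, 0.1, tag

        ranked = select_model([Fit("a"), Fit("b")])
        assert [f.tag for f in ranked] == ["a", "b"]


class TestBand:
    def test_zero_width_interval_collapses(self):
        from htarisk.fncurve import FNSeries

        N = np.array([1, 2, 4, 8, 16])
        series = FNSeries(N, np.ones(5, int), 1.0 * N ** (-2.0))
        band = fn_band(fit_powerlaw_loglog(series), series)
        N_eval = np.geomspace(1, 50, 20)
        vals = band.evaluate(N_eval)
        assert np.allclose(vals["lower"], vals["central"], rtol=1e-6)
        assert np.allclose(vals["upper"], vals["central"], rtol=1e-6)

    def test_slope_fit_band_uses_population_interval(self, china_slopes, china_series):
        band = fn_band(fit_normal(china_slopes), china_series)
        assert band.lower[0] == pytest.approx(1.5217, abs=5e-4)
        assert band.upper[0] == pytest.approx(1.1631, abs=5e-4)

    def test_nesting_everywhere(self, china_series, china_slopes):
        for fit in (fit_powerlaw_linear(china_series), fit_powerlaw_loglog(china_series), fit_normal(china_slopes)):
            band = fn_band(fit, china_series)
            vals = band.evaluate(np.geomspace(1, 58, 40))
            assert np.all(vals["lower"] <= vals["central"] + 1e-12)
            assert np.all(vals["central"] <= vals["upper"] + 1e-12)


class TestFatalityRatio:
    @pytest.mark.parametrize(
        "a,n1,n2,expected,tol",
        [
            (1.1631, 10, 100, 14.56, 0.01),
            (1.5217, 10, 100, 33.24, 0.01),
            (1.0, 4, 36, 9.0, 1e-12),
        ],
    )
    def test_power_law_ratio(self, a, n1, n2, expected, tol):
        assert fatality_ratio(a, n1, n2) == pytest.approx(expected, abs=tol)

    def test_argument_contracts(self):
        with pytest.raises(ValueError):
            fatality_ratio(1.0, 10, 10)
        with pytest.raises(ValueError):
            fatality_ratio(-1.0, 1, 10)


class TestBootstrapInterval:
    def test_contains_truth_for_clean_tail(self):
        deaths = generate_deaths(800, a_star=1.3, seed=42)
        lo, hi = bootstrap_slope_interval(deaths, n_boot=199, seed=7)
        assert lo < 1.3 < hi
        assert hi - lo < 1.0

    def test_rejects_nonfatal(self):
        with pytest.raises(ValueError):
            bootstrap_slope_interval([0, 1, 2])
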