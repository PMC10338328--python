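"""Lethal concentrations, lethal-dose density, variability and fit statistics."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import bioassayfit as bf
from bioassayfit.metrics import (
    LCEstimate,
    fitted_mortality,
    mean_absolute_deviation,
)


def lc_by_bisection(params: bf.CurveParams, q: float) -> float:
    """Independent numerical inversion of the background-corrected curve."""

    def f(log_conc):
        p = bf.mean_mortality(params, math.exp(log_conc))
        return p - (params.A + q * (1 - params.A))

    return math.exp(brentq(f, -200, 200, xtol=1e-14, rtol=1e-15))


class TestLcQuantile:
    def test_symmetric_midpoint_closed_form(self):
        # q = 1/2, E = 1: model-scale LC is exactly e^C, concentration e^{2C}
        p = bf.CurveParams(A=0.02, B=5, C=0.3, E=1)
        assert bf.lc_quantile(p, 0.5) == pytest.approx(math.exp(0.6), rel=1e-12)

    def test_worked_value_matches_bisection(self):
        p = bf.CurveParams(A=0.05, B=5, C=0.2, E=7)
        lc = bf.lc_quantile(p, 0.5)
        assert lc == pytest.approx(lc_by_bisection(p, 0.5), rel=1e-10)
        assert math.sqrt(lc) == pytest.approx(0.7768, abs=2e-4)
        assert lc == pytest.approx(0.6034, abs=2e-4)

    def test_ordering_in_q(self):
        p = bf.CurveParams(A=0.05, B=5, C=0.2, E=7)
        assert bf.lc_quantile(p, 0.1) < bf.lc_quantile(p, 0.5) < bf.lc_quantile(p, 0.9)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2, 1.3])
    def test_quantile_domain(self, q):
        with pytest.raises(ValueError):
            bf.lc_quantile(bf.CurveParams(A=0.05, B=5, C=0.2, E=7), q)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        b=st.floats(0.5, 10),
        c=st.floats(-6, 3),
        e=st.floats(0.3, 10),
        q=st.floats(0.02, 0.98),
    )
    def test_closed_form_equals_numerical_inversion(self, b, c, e, q):
        p = bf.CurveParams(A=0.05, B=b, C=c, E=e)
        assert bf.lc_quantile(p, q) == pytest.approx(
            lc_by_bisection(p, q), rel=1e-8
        )

    def test_independent_of_background(self):
        ref = bf.lc_quantile(bf.CurveParams(A=0.001, B=4, C=-1, E=3), 0.3)
        for a in (0.05, 0.3):
            got = bf.lc_quantile(bf.CurveParams(A=a, B=4, C=-1, E=3), 0.3)
            assert got == pytest.approx(ref, rel=1e-12)

    def test_temporal_params_require_year(self):
        lin = bf.LinearTimeParams(A=0.05, B=4, E=5, F=0.0, G=0.1, t0=2016)
        with pytest.raises(ValueError, match="year"):
            bf.lc_quantile(lin, 0.5)
        assert bf.lc_quantile(lin, 0.5, year=2018) == pytest.approx(
            bf.lc_quantile(lin.curve_for_year(2018), 0.5)
        )


class TestLcPosterior:
    def test_degenerate_posterior(self, degenerate_samples_factory):
        samples = degenerate_samples_factory(0.05, 5, -1.0, 7)
        est = bf.lc_posterior(samples, 0.5)
        expected = bf.lc_quantile(bf.CurveParams(A=0.05, B=5, C=-1.0, E=7), 0.5)
        assert est.point == pytest.approx(expected)
        assert est.interval == (pytest.approx(expected), pytest.approx(expected))

    def test_location_shift_equivariance(self, lab_fit):
        delta = 0.4
        base = bf.lc_posterior(lab_fit.posterior, 0.5)
        shifted_draws = dict(lab_fit.posterior.draws)
        shifted_draws["C"] = shifted_draws["C"] + delta
        shifted = bf.PosteriorSamples(
            shifted_draws,
            lab_fit.posterior.log_lik_chains,
            lab_fit.posterior.config,
            "base",
        )
        est = bf.lc_posterior(shifted, 0.5)
        assert np.allclose(est.draws, base.draws * math.exp(2 * delta), rtol=1e-10)

    def test_per_draw_ordering(self, lab_fit):
        lc10 = bf.lc_posterior(lab_fit.posterior, 0.1).draws
        lc50 = bf.lc_posterior(lab_fit.posterior, 0.5).draws
        lc90 = bf.lc_posterior(lab_fit.posterior, 0.9).draws
        assert np.all(lc10 < lc50) and np.all(lc50 < lc90)

    def test_temporal_samples_need_year(self, degenerate_samples_factory):
        samples = degenerate_samples_factory(0.05, 5, -1.0, 7)
        samples.variant = "linear_time"
        with pytest.raises(ValueError, match="year"):
            bf.lc_posterior(samples, 0.5)


class TestLethalDoseSamples:
    def test_inverse_transform_identity_on_degenerate_posterior(
        self, degenerate_samples_factory
    ):
        samples = degenerate_samples_factory(0.05, 5, -1.0, 7, n_kept=100)
        params = bf.CurveParams(A=0.05, B=5, C=-1.0, E=7)
        draws = bf.lethal_dose_samples(samples, 100000, seed=3)
        assert np.all(draws > 0)
        for q in (0.1, 0.5, 0.9):
            ecdf = np.mean(draws <= bf.lc_quantile(params, q))
            # Dvoretzky-Kiefer-Wolfowitz: P(sup|F_n - F| > eps) <= 2 exp(-2 n eps^2)
            eps = math.sqrt(math.log(2 / 1e-6) / (2 * 100000))
            assert abs(ecdf - q) < eps

    def test_median_matches_lc50_posterior(self, lab_fit):
        draws = lab_fit.lethal_dose_samples(100000, seed=11)
        lc50 = lab_fit.lc(0.5)
        spread = np.diff(np.percentile(draws, [40, 60]))[0]
        assert np.median(draws) == pytest.approx(lc50.point, abs=3 * spread / 10 + 0.02 * lc50.point)

    def test_seeded(self, degenerate_samples_factory):
        samples = degenerate_samples_factory(0.05, 5, -1.0, 7)
        a = bf.lethal_dose_samples(samples, 100, seed=5)
        b = bf.lethal_dose_samples(samples, 100, seed=5)
        assert np.array_equal(a, b)


class TestVariability:
    def test_worked_two_point_example(self, degenerate_samples_factory):
        # observed {20%, 40%}, fitted {30%, 50%} -> (10 + 10) / 2 = 10
        params = bf.CurveParams(A=0.05, B=1, C=0.0, E=1)
        conc = [
            bf.lc_quantile(params, (0.30 - 0.05) / 0.95),
            bf.lc_quantile(params, (0.50 - 0.05) / 0.95),
        ]
        ds = bf.BioassayDataset(
            [
                bf.BioassayRecord(conc[0], 10, 2),
                bf.BioassayRecord(conc[1], 10, 4),
            ]
        )
        samples = degenerate_samples_factory(0.05, 1, 0.0, 1, n_records=2)
        est = bf.variability(ds, samples)
        assert est.median == pytest.approx(10.0, abs=1e-8)

    def test_eight_point_mean_absolute_deviation(self):
        devs = np.array([2, 3, 5, 1, 4, 6, 2, 1], dtype=float)
        assert mean_absolute_deviation(50 + devs, np.full(8, 50.0)) == 3.0

    def test_perfect_fit_is_zero(self, degenerate_samples_factory):
        params = bf.CurveParams(A=0.05, B=5, C=-1.0, E=7)
        n = 10**6
        recs = [
            bf.BioassayRecord(c, n, round(bf.mean_mortality(params, c) * n))
            for c in (0.05, 0.2)
        ]
        samples = degenerate_samples_factory(0.05, 5, -1.0, 7, n_records=2)
        est = bf.variability(bf.BioassayDataset(recs), samples)
        assert est.median == pytest.approx(0.0, abs=1e-3)

    def test_order_invariance_and_linear_scaling(self):
        obs = np.array([20.0, 45.0, 70.0, 90.0])
        fit = np.array([25.0, 40.0, 72.0, 88.0])
        v = mean_absolute_deviation(obs, fit)
        perm = [2, 0, 3, 1]
        assert mean_absolute_deviation(obs[perm], fit[perm]) == pytest.approx(v)
        assert mean_absolute_deviation(fit + 3 * (obs - fit), fit) == pytest.approx(3 * v)


class TestFitStatistics:
    def _dataset_and_samples(self, factory):
        # A -> 0, B=1, C=0, E=1: p = u/(1+u) with u the model-scale dose
        samples = factory(1e-9, 1.0, 0.0, 1.0, n_records=3)
        conc = [0.0625, 1.0, 16.0]  # p = 0.2, 0.5, 0.8
        ds = bf.BioassayDataset(
            [
                bf.BioassayRecord(conc[0], 10, 1),
                bf.BioassayRecord(conc[1], 10, 5),
                bf.BioassayRecord(conc[2], 10, 9),
            ]
        )
        return ds, samples

    def test_toy_rmse_and_r2(self, degenerate_samples_factory):
        # obs {10, 50, 90}%, fitted {20, 50, 80}% -> RMSE = sqrt(200/3)
        ds, samples = self._dataset_and_samples(degenerate_samples_factory)
        stats_ = bf.fit_statistics(ds, samples)
        assert stats_["rmse"] == pytest.approx(math.sqrt(200 / 3), abs=1e-6)
        assert stats_["r2"] == pytest.approx(1 - 200 / 3200, abs=1e-6)

    def test_constant_fit_gives_zero_r2(self, degenerate_samples_factory):
        samples = degenerate_samples_factory(0.5, 1.0, 0.0, 1.0, n_records=2)
        ds = bf.BioassayDataset(
            [bf.BioassayRecord(0.0, 10, 4), bf.BioassayRecord(0.0, 10, 6)]
        )
        stats_ = bf.fit_statistics(ds, samples)
        assert stats_["r2"] == pytest.approx(0.0)

    def test_zero_variance_observations_undefined(self, degenerate_samples_factory):
        samples = degenerate_samples_factory(0.3, 1.0, 0.0, 1.0, n_records=2)
        ds = bf.BioassayDataset(
            [bf.BioassayRecord(0.0, 10, 5), bf.BioassayRecord(0.0, 10, 5)]
        )
        with pytest.warns(RuntimeWarning):
            stats_ = bf.fit_statistics(ds, samples)
        assert math.isnan(stats_["r2"])

    def test_good_fit_on_simulated_data(self, lab_fit):
        stats_ = lab_fit.fit_statistics()
        assert stats_["r2"] > 0.9 and stats_["rmse"] < 15


class TestCompareLc:
    def test_disjoint_supports(self):
        a = LCEstimate(0.5, np.linspace(10, 11, 200))
        b = LCEstimate(0.5, np.linspace(1, 2, 200))
        assert bf.compare_lc(a, b, n_pairs=1000, seed=0).probability == 1.0

    def test_identical_distributions_near_half(self):
        draws = np.random.default_rng(3).lognormal(0, 0.5, 5000)
        p = bf.compare_lc(LCEstimate(0.5, draws), LCEstimate(0.5, draws),
                          n_pairs=100000, seed=1).probability
        assert p == pytest.approx(0.5, abs=0.01)

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(8)
        a = LCEstimate(0.5, rng.lognormal(0.0, 0.1, 200000))
        b = LCEstimate(0.5, rng.lognormal(0.2, 0.1, 200000))
        from scipy.stats import norm

        expected = norm.cdf(-0.2 / (0.1 * math.sqrt(2)))
        got = bf.compare_lc(a, b, n_pairs=100000, seed=2).probability
        assert got == pytest.approx(expected, abs=0.01)


class TestBackgroundMortality:
    def test_degenerate(self, degenerate_samples_factory):
        s = degenerate_samples_factory(0.09, 5, -1.0, 7)
        out = bf.background_mortality_summary(s)
        assert out["mean"] == pytest.approx(9.0)
        assert out["lower"] == pytest.approx(out["upper"])

    def test_arithmetic_mean(self, degenerate_samples_factory):
        s = degenerate_samples_factory(0.09, 5, -1.0, 7)
        s.draws["A"] = np.array([[0.01, 0.02, 0.03, 0.02], [0.02, 0.03, 0.01, 0.02]])
        assert bf.background_mortality_summary(s)["mean"] == pytest.approx(2.0)

    def test_recovery_on_simulated_data(self, lab_dataset, lab_fit):
        spec, _ = lab_dataset
        out = lab_fit.background_mortality()
        assert out["lower"] <= spec.truth.A * 100 <= out["upper"]


class TestFittedMortality:
    def test_matches_mean_mortality_per_draw(self, degenerate_samples_factory):
        params = bf.CurveParams(A=0.05, B=5, C=-1.0, E=7)
        ds = bf.BioassayDataset(
            [bf.BioassayRecord(c, 10, 5) for c in (0.0, 0.05, 0.3)]
        )
        samples = degenerate_samples_factory(0.05, 5, -1.0, 7, n_records=3)
        mat = fitted_mortality(samples, ds)
        expected = [bf.mean_mortality(params, c) for c in (0.0, 0.05, 0.3)]
        assert np.allclose(mat, np.array(expected)[None, :])
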