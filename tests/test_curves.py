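"""The 5PL functional forms, priors and binomial likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import bioassayfit as bf
from bioassayfit.curves import binomial_logpmf, default_priors

valid_params = st.builds(
    bf.CurveParams,
    A=st.floats(0.001, 0.5),
    B=st.floats(0.2, 12.0),
    C=st.floats(-6.0, 3.0),
    E=st.floats(0.2, 12.0),
)


class TestTransform:
    @pytest.mark.parametrize("c,expected", [(0.25, 0.5), (0.0, 0.0), (1.0, 1.0)])
    def test_square_root(self, c, expected):
        assert bf.transform_concentration(c) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bf.transform_concentration(-0.1)


class TestMeanMortality:
    def test_control_returns_background_exactly(self):
        p = bf.CurveParams(A=0.07, B=5, C=0.2, E=7)
        assert bf.mean_mortality(p, 0.0) == 0.07

    def test_symmetric_midpoint(self):
        # E=1, A=0, dose at the location: (x=1, ln x = 0, C=0) -> 0.5
        p = bf.CurveParams(A=1e-12, B=1, C=0, E=1)
        assert bf.mean_mortality(p, 1.0) == pytest.approx(0.5, abs=1e-9)

    def test_direct_substitution_oracle(self):
        # u = e^-1, p = 1 - 0.95 / (1 + u)^7, evaluated independently
        p = bf.CurveParams(A=0.05, B=5, C=0.2, E=7)
        expected = 1.0 - 0.95 / (1.0 + math.exp(-1.0)) ** 7
        assert bf.mean_mortality(p, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.894, abs=5e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(params=valid_params, c1=st.floats(1e-8, 10), c2=st.floats(1e-8, 10))
    def test_monotone_in_concentration(self, params, c1, c2):
        lo, hi = sorted([c1, c2])
        assert bf.mean_mortality(params, lo) <= bf.mean_mortality(params, hi) + 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.001, 0.5),
        b=st.floats(0.2, 12.0),
        c=st.floats(-6.0, 3.0),
        e=st.floats(1.0, 12.0),
    )
    def test_upper_asymptote(self, a, b, c, e):
        # dose where e^{B (ln x - C)} > 1e8 puts mortality within 1e-6 of 1
        # (for E >= 1; smaller asymmetry flattens the approach to the asymptote)
        params = bf.CurveParams(A=a, B=b, C=c, E=e)
        lnx = params.C + (8 * math.log(10) + 1) / params.B
        conc = math.exp(2 * lnx)
        assert bf.mean_mortality(params, conc) > 1 - 1e-6

    def test_symmetric_logistic_identity(self):
        # with E = 1: p(x1) + p(x2) = A + 1 when ln x1 - C = -(ln x2 - C)
        p = bf.CurveParams(A=0.1, B=3.0, C=-0.5, E=1.0)
        for delta in (0.3, 1.0, 2.5):
            x1 = math.exp(2 * (p.C - delta))
            x2 = math.exp(2 * (p.C + delta))
            total = bf.mean_mortality(p, x1) + bf.mean_mortality(p, x2)
            assert total == pytest.approx(p.A + 1.0, abs=1e-10)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(A=0), dict(A=1), dict(B=0), dict(B=-1), dict(E=0)],
    )
    def test_invalid_params_rejected(self, kwargs):
        base = dict(A=0.05, B=5, C=0.0, E=7)
        with pytest.raises(ValueError):
            bf.CurveParams(**{**base, **kwargs})


class TestTemporalVariants:
    grid = [0.0, 0.01, 0.1, 0.5, 1.0, 4.0]

    def test_linear_reduces_to_base_when_flat(self):
        base = bf.CurveParams(A=0.05, B=4, C=0.3, E=5)
        lin = bf.LinearTimeParams(A=0.05, B=4, E=5, F=0.3, G=0.0, t0=2016)
        for c in self.grid:
            for year in (2016, 2019, 2021):
                assert bf.mean_mortality_temporal(lin, c, year) == bf.mean_mortality(
                    base, c
                )

    def test_individual_reduces_when_all_equal(self):
        base = bf.CurveParams(A=0.05, B=4, C=0.3, E=5)
        ind = bf.IndividualTimeParams(
            A=0.05, B=4, E=5, C_by_year={2016: 0.3, 2017: 0.3}
        )
        for c in self.grid:
            assert bf.mean_mortality_temporal(ind, c, 2017) == bf.mean_mortality(base, c)

    def test_base_time_reduces_when_all_equal(self):
        base = bf.CurveParams(A=0.05, B=4, C=0.3, E=5)
        bt = bf.BaseTimeParams({2016: base, 2021: base})
        for c in self.grid:
            assert bf.mean_mortality_temporal(bt, c, 2021) == bf.mean_mortality(base, c)

    def test_rightward_shift_lowers_mortality(self):
        ind = bf.IndividualTimeParams(
            A=0.05, B=4, E=5, C_by_year={2016: 0.1, 2021: 0.3}
        )
        assert bf.mean_mortality_temporal(ind, 1.0, 2021) < bf.mean_mortality_temporal(
            ind, 1.0, 2016
        )

    def test_linear_time_direct_substitution(self):
        # A=0, B=5, E=1, F=0, G=0.1, t=2, conc 1: p = 1 - 1/(1 + e^-1)
        lin = bf.LinearTimeParams(A=1e-15, B=5, E=1, F=0.0, G=0.1, t0=2016)
        expected = 1.0 - 1.0 / (1.0 + math.exp(-1.0))
        assert bf.mean_mortality_temporal(lin, 1.0, 2018) == pytest.approx(
            expected, rel=1e-9
        )
        assert expected == pytest.approx(0.2689, abs=1e-4)

    def test_unseen_year_rejected(self):
        ind = bf.IndividualTimeParams(A=0.05, B=4, E=5, C_by_year={2016: 0.1})
        with pytest.raises(KeyError, match="2020"):
            bf.mean_mortality_temporal(ind, 1.0, 2020)


class TestLogLikelihood:
    def test_single_bernoulli(self):
        assert binomial_logpmf(1, 1, 0.5) == pytest.approx(math.log(0.5))

    def test_clamp_keeps_finite(self):
        assert np.isfinite(binomial_logpmf(5, 10, 1.0))
        assert np.isfinite(binomial_logpmf(5, 10, 0.0))

    def test_two_record_oracle(self):
        # independent hand-computed pmf: C(10,3) 0.3^3 0.7^7 (symmetric pair)
        hand = math.log(math.comb(10, 3)) + 3 * math.log(0.3) + 7 * math.log(0.7)
        got = binomial_logpmf(3, 10, 0.3) + binomial_logpmf(7, 10, 0.7)
        assert got == pytest.approx(2 * hand, rel=1e-12)
        assert got == pytest.approx(
            stats.binom.logpmf(3, 10, 0.3) + stats.binom.logpmf(7, 10, 0.7),
            rel=1e-12,
        )

    def test_dataset_log_likelihood_matches_scipy(self):
        from bioassayfit.curves import LIKELIHOOD_EPS

        params = bf.CurveParams(A=0.05, B=2, C=-1.5, E=2)
        ds = bf.BioassayDataset(
            [
                bf.BioassayRecord(0.0, 25, 1),
                bf.BioassayRecord(0.01, 25, 9),
                bf.BioassayRecord(0.1, 25, 24),
            ]
        )
        p = [
            np.clip(
                bf.mean_mortality(params, r.concentration),
                LIKELIHOOD_EPS,
                1 - LIKELIHOOD_EPS,
            )
            for r in ds
        ]
        expected = sum(
            stats.binom.logpmf(r.n_dead, r.n_tested, pi) for r, pi in zip(ds, p)
        )
        total, pointwise = bf.log_likelihood(params, ds)
        assert total == pytest.approx(expected, rel=1e-10)
        assert pointwise.sum() == pytest.approx(total)
        assert pointwise.shape == (3,)


class TestLogPrior:
    def test_outside_support_is_neg_inf(self):
        priors = default_priors()
        params = bf.CurveParams(A=0.05, B=5, C=0.0, E=7)
        assert np.isfinite(bf.log_prior(params, priors))
        assert priors["B"].logpdf(-0.1) == -math.inf

    def test_normal_mode_value(self):
        assert default_priors()["C"].logpdf(0.0) == pytest.approx(
            stats.norm.logpdf(0.0, 0.0, 5.0)
        )

    def test_truncated_background_prior_oracle(self):
        # A ~ N+(0, 0.1) truncated to (0, 1): cross-check against scipy truncnorm
        entry = default_priors()["A"]
        oracle = stats.truncnorm(0.0, 10.0, loc=0.0, scale=0.1)
        for a in (0.01, 0.05, 0.3, 0.9):
            assert entry.logpdf(a) == pytest.approx(oracle.logpdf(a), rel=1e-10)
        # essentially log[2 phi(0.5)/0.1] since the upper truncation is negligible
        assert entry.logpdf(0.05) == pytest.approx(
            math.log(2 * stats.norm.pdf(0.5) / 0.1), abs=1e-10
        )

    def test_sum_over_free_parameters(self):
        priors = default_priors()
        params = bf.CurveParams(A=0.05, B=5, C=1.0, E=7)
        expected = (
            priors["A"].logpdf(0.05)
            + priors["B"].logpdf(5.0)
            + priors["C"].logpdf(1.0)
            + priors["E"].logpdf(7.0)
        )
        assert bf.log_prior(params, priors) == pytest.approx(float(expected))


class TestPriorPredictive:
    def test_seeded_and_deterministic(self):
        priors = default_priors()
        c1, p1 = bf.prior_predictive_sample(priors, [0, 0.1, 1], 3, seed=9)
        c2, p2 = bf.prior_predictive_sample(priors, [0, 0.1, 1], 3, seed=9)
        assert np.array_equal(c1, c2) and p1 == p2

    def test_asymptotes(self):
        curves, params = bf.prior_predictive_sample(
            default_priors(), [0.0, 1e12], 50, seed=3
        )
        assert np.allclose(curves[:, 0], [p.A for p in params])
        assert np.all(curves[:, 1] > 1 - 1e-3)

    def test_location_prior_mean(self):
        _, params = bf.prior_predictive_sample(default_priors(), [0.1], 10000, seed=1)
        c = np.array([p.C for p in params])
        # C ~ N(0, 5): sample mean within 4 standard errors of 0
        assert abs(c.mean()) < 4 * 5 / math.sqrt(10000)
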