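"""Distribution functions and censored log-likelihood derivatives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from gebayes import (
    GEParams,
    SurvivalSample,
    censored_loglik,
    ge_cdf,
    ge_pdf,
    ge_quantile,
    ge_survival,
    loglik_derivatives,
)

LN2 = math.log(2.0)


class TestPointValues:
    @pytest.mark.parametrize(
        "theta,p,t,expected",
        [
            (1.0, 1.0, LN2, 0.5),      # exponential median
            (1.0, 2.0, LN2, 0.25),     # (1 - 1/2)^2
            (2.0, 3.0, 0.0, 0.0),      # boundary
        ],
    )
    def test_cdf(self, theta, p, t, expected):
        assert ge_cdf(GEParams(theta, p), t) == pytest.approx(expected, abs=1e-12)

    def test_pdf_exponential_case(self):
        assert ge_pdf(GEParams(1.0, 1.0), 1.0) == pytest.approx(math.exp(-1), rel=1e-12)

    @pytest.mark.parametrize(
        "theta,p,u,expected",
        [
            (1.0, 1.0, 0.5, LN2),
            (1.0, 2.0, 0.25, LN2),
            (3.0, 0.7, 0.0, 0.0),
        ],
    )
    def test_quantile(self, theta, p, u, expected):
        assert ge_quantile(GEParams(theta, p), u) == pytest.approx(expected, abs=1e-12)

    def test_survival_boundary_and_complement(self, rng):
        params = GEParams(0.9, 1.7)
        assert ge_survival(params, 0.0) == 1.0
        t = rng.uniform(0.01, 10, size=100)
        np.testing.assert_allclose(
            ge_survival(params, t) + ge_cdf(params, t), 1.0, atol=1e-12
        )

    def test_pdf_is_cdf_derivative(self):
        params = GEParams(1.3, 2.4)
        h = 1e-5
        num = (ge_cdf(params, 0.7 + h) - ge_cdf(params, 0.7 - h)) / (2 * h)
        assert num == pytest.approx(ge_pdf(params, 0.7), abs=1e-6)

    def test_pdf_integrates_to_one(self):
        params = GEParams(2.0, 0.8)
        val, err = integrate.quad(lambda t: ge_pdf(params, t), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_exponentiated_weibull(self, rng):
        # GE(theta, p) is exponweib with a=p, c=1, scale=1/theta
        params = GEParams(0.7, 3.1)
        t = rng.uniform(0.05, 8, size=50)
        np.testing.assert_allclose(
            ge_cdf(params, t),
            stats.exponweib.cdf(t, params.p, 1, scale=1 / params.theta),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            ge_pdf(params, t),
            stats.exponweib.pdf(t, params.p, 1, scale=1 / params.theta),
            rtol=1e-10,
        )


class TestDomainErrors:
    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GEParams(-1.0, 2.0)
        with pytest.raises(ValueError):
            GEParams(1.0, 0.0)
        with pytest.raises(ValueError):
            GEParams(np.nan, 1.0)

    def test_invalid_times(self):
        params = GEParams(1.0, 1.0)
        with pytest.raises(ValueError):
            ge_cdf(params, -1.0)
        with pytest.raises(ValueError):
            ge_cdf(params, np.inf)
        with pytest.raises(ValueError):
            ge_pdf(params, 0.0)

    def test_invalid_probability(self):
        params = GEParams(1.0, 1.0)
        for u in (-0.1, 1.0, 1.5, np.nan):
            with pytest.raises(ValueError):
                ge_quantile(params, u)

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            SurvivalSample(np.array([1.0, -2.0]), np.array([1, 0]))
        with pytest.raises(ValueError):
            SurvivalSample(np.array([1.0]), np.array([2]))
        with pytest.raises(ValueError):  # event at time zero
            SurvivalSample(np.array([0.0]), np.array([1]))
        # censored at zero is allowed
        SurvivalSample(np.array([0.0, 1.0]), np.array([0, 1]))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    theta=st.floats(0.05, 20.0),
    p=st.floats(0.05, 20.0),
    u=st.floats(1e-6, 1.0 - 1e-9),
)
def test_quantile_cdf_roundtrip(theta, p, u):
    params = GEParams(theta, p)
    assert ge_cdf(params, ge_quantile(params, u)) == pytest.approx(u, abs=1e-10)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(theta=st.floats(0.1, 5.0), p=st.floats(0.1, 5.0))
def test_cdf_monotone_with_limits(theta, p):
    params = GEParams(theta, p)
    grid = np.linspace(0, 80.0 / theta, 200)
    vals = ge_cdf(params, grid)
    assert np.all(np.diff(vals) >= -1e-14)
    assert vals[0] == 0.0
    assert vals[-1] == pytest.approx(1.0, abs=1e-8)


class TestCensoredLoglik:
    def test_hand_value_exponential(self, tiny_sample):
        # theta=0.5, p=1: log f(1) + log S(2) = log .5 - .5 - 1
        val = censored_loglik(GEParams(0.5, 1.0), tiny_sample)
        assert val == pytest.approx(math.log(0.5) - 0.5 - 1.0, abs=1e-12)

    def test_complete_data_reduction(self, rng):
        t = rng.uniform(0.1, 5, size=30)
        sample = SurvivalSample(t, np.ones(30, dtype=int))
        params = GEParams(0.8, 1.9)
        assert censored_loglik(params, sample) == pytest.approx(
            float(np.sum(np.log(ge_pdf(params, t)))), rel=1e-12
        )

    def test_term_by_term_against_scipy(self, sample_n20):
        # independent route: scipy's exponentiated-Weibull logpdf/logsf
        params = GEParams(1.1, 2.2)
        t, d = sample_n20.times, sample_n20.events.astype(bool)
        ref = stats.exponweib.logpdf(t[d], params.p, 1, scale=1 / params.theta).sum()
        ref += stats.exponweib.logsf(t[~d], params.p, 1, scale=1 / params.theta).sum()
        assert censored_loglik(params, sample_n20) == pytest.approx(ref, rel=1e-12)

    def test_time_rescaling_identity(self, sample_n50):
        # rescaling t -> c t and theta -> theta/c preserves the surface up
        # to the Jacobian constant -d log c (one per observed event), so the
        # maximiser maps exactly and the p-profile is unchanged
        params = GEParams(0.9, 1.4)
        d = sample_n50.n_events
        for c in (0.25, 3.0, 17.0):
            scaled = SurvivalSample(sample_n50.times * c, sample_n50.events)
            assert censored_loglik(
                GEParams(params.theta / c, params.p), scaled
            ) == pytest.approx(
                censored_loglik(params, sample_n50) - d * math.log(c), rel=1e-10
            )


def _fd_gradient(f, x, h=1e-6):
    g = np.zeros(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = h * max(1.0, abs(x[i]))
        g[i] = (f(x + e) - f(x - e)) / (2 * e[i])
    return g


class TestDerivatives:
    @pytest.fixture
    def point(self):
        return np.array([1.3, 2.4])

    def test_gradient_matches_finite_difference(self, sample_n20, point):
        f = lambda x: censored_loglik(GEParams(*x), sample_n20)
        bundle = loglik_derivatives(GEParams(*point), sample_n20, order=1)
        np.testing.assert_allclose(
            bundle.gradient, _fd_gradient(f, point), rtol=1e-6
        )

    def test_hessian_matches_finite_difference(self, sample_n20, point):
        bundle = loglik_derivatives(GEParams(*point), sample_n20, order=2)
        for j in range(2):
            fd = _fd_gradient(
                lambda x: loglik_derivatives(GEParams(*x), sample_n20, 1).gradient[j],
                point,
            )
            np.testing.assert_allclose(bundle.hessian[j], fd, rtol=1e-5)

    def test_third_matches_finite_difference(self, sample_n20, point):
        bundle = loglik_derivatives(GEParams(*point), sample_n20, order=3)
        for j in range(2):
            for k in range(2):
                fd = _fd_gradient(
                    lambda x: loglik_derivatives(
                        GEParams(*x), sample_n20, 2
                    ).hessian[j, k],
                    point,
                )
                np.testing.assert_allclose(
                    bundle.third[j, k], fd, rtol=1e-4, atol=1e-8
                )

    def test_tensor_symmetry_exact(self, sample_n20, point):
        bundle = loglik_derivatives(GEParams(*point), sample_n20, order=3)
        assert bundle.hessian[0, 1] == bundle.hessian[1, 0]
        T = bundle.third
        import itertools

        for idx in itertools.product(range(2), repeat=3):
            for perm in itertools.permutations(idx):
                assert T[idx] == T[perm]

    def test_exponential_special_case(self, sample_n50):
        # at p=1 the theta-gradient is sum(delta)/theta - sum(t)
        theta = 0.6
        bundle = loglik_derivatives(GEParams(theta, 1.0), sample_n50, order=1)
        expected = sample_n50.n_events / theta - sample_n50.times.sum()
        assert bundle.gradient[0] == pytest.approx(expected, rel=1e-10)

    def test_exponential_collapse_distribution(self):
        params = GEParams(0.7, 1.0)
        t = np.linspace(0.1, 6, 40)
        np.testing.assert_allclose(
            ge_cdf(params, t), stats.expon.cdf(t, scale=1 / 0.7), atol=1e-10
        )
        np.testing.assert_allclose(
            ge_pdf(params, t), stats.expon.pdf(t, scale=1 / 0.7), atol=1e-10
        )
        u = np.linspace(0, 0.99, 20)
        np.testing.assert_allclose(
            ge_quantile(params, u), stats.expon.ppf(u, scale=1 / 0.7), atol=1e-10
        )
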