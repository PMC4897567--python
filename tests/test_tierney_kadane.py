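"""Tierney-Kadane ratio approximation: exactness, oracle agreement, orderings."""

import numpy as np
import pytest

from gebayes import (
    GammaPriors,
    LossSpec,
    lindley_estimate,
    load_fixture,
    oracle_expectation,
    tk_estimate,
    tk_expectation,
)
from gebayes.tierney_kadane import (
    LogEstimand,
    _TKWorkspace,
    log_estimand,
    tk_expectation_exponential,
    tk_joint_product_expectation,
)
from tests.conftest import make_censored_sample


def test_unit_estimand_returns_one(sample_n50, flat_priors):
    unit = LogEstimand(
        logv=lambda th, p: 0.0,
        grad=lambda th, p: np.zeros(2),
        hess_diag=lambda th, p: np.zeros(2),
    )
    assert tk_expectation(sample_n50, flat_priors, unit) == pytest.approx(1.0, abs=1e-9)


def test_positive_estimands_give_positive_values(sample_n50, zero_priors):
    ws = _TKWorkspace(sample_n50, zero_priors)
    for kind, which, k in (
        ("identity", "theta", 0.0),
        ("identity", "p", 0.0),
        ("square", "p", 0.0),
        ("linex", "p", 0.7),
        ("linex", "theta", -0.7),
    ):
        val = ws.expectation(log_estimand(kind, which, k))
        assert np.isfinite(val) and val > 0


def test_conjugate_exponential_submodel():
    """Shape-known sub-model: the ratio approximation vs Gamma closed forms."""
    s = make_censored_sample(100, theta=1.2, p=1.0, seed=11)
    a, b = 2.0, 3.0
    d, T = s.n_events, float(s.times.sum())
    exact_mean = (b + d) / (a + T)
    assert tk_expectation_exponential(s, a, b) == pytest.approx(exact_mean, rel=1e-3)
    for k in (0.7, -0.7):
        exact_moment = ((a + T) / (a + T + k)) ** (b + d)
        assert tk_expectation_exponential(s, a, b, k=k) == pytest.approx(
            exact_moment, rel=1e-3
        )


def test_matches_oracle_on_simulated_sample(sample_n50, flat_priors):
    approx = tk_expectation(sample_n50, flat_priors, log_estimand("identity", "p"))
    exact = oracle_expectation(sample_n50, flat_priors, lambda th, p: p).value
    assert approx == pytest.approx(exact, rel=1e-2)


def test_ratio_beats_plain_laplace(sample_n50, flat_priors):
    """The ratio form should outperform evaluating the estimand at the
    posterior mode (the zeroth-order Laplace answer)."""
    ws = _TKWorkspace(sample_n50, flat_priors)
    tk_val = ws.expectation(log_estimand("identity", "p"))
    plain = ws.params_base.p  # estimand at the posterior mode, no ratio
    exact = oracle_expectation(sample_n50, flat_priors, lambda th, p: p).value
    assert abs(tk_val - exact) < abs(plain - exact)


def test_agreement_with_lindley_shrinks_in_n(flat_priors):
    gaps = []
    for n in (25, 100, 400):
        s = make_censored_sample(n, theta=1.0, p=2.0, seed=21)
        tk = tk_estimate(s, flat_priors, LossSpec("SEL"), with_sd=False)
        lin = lindley_estimate(s, flat_priors, LossSpec("SEL"))
        gaps.append(abs(tk.p - lin.p))
    assert gaps[2] < gaps[1] < gaps[0]


class TestEstimates:
    def test_linex_converges_to_sel(self, sample_n50, zero_priors):
        """As k -> 0 the two LINEX estimates collapse onto a common limit;
        that limit agrees with the SEL estimate up to the method's own
        O(1/n^2) resolution (the two use differently tilted surfaces, so
        exact coincidence at finite n is not a property of the method)."""
        ws = _TKWorkspace(sample_n50, zero_priors)
        sel = tk_estimate(sample_n50, zero_priors, LossSpec("SEL"),
                          workspace=ws, with_sd=False)
        plus = tk_estimate(sample_n50, zero_priors, LossSpec("LINEX", 1e-6),
                           workspace=ws, with_sd=False)
        minus = tk_estimate(sample_n50, zero_priors, LossSpec("LINEX", -1e-6),
                            workspace=ws, with_sd=False)
        n = sample_n50.n
        for attr in ("theta", "p"):
            assert abs(getattr(plus, attr) - getattr(minus, attr)) < 1e-5
            envelope = 30.0 * max(1.0, getattr(sel, attr)) / n**2
            assert abs(getattr(plus, attr) - getattr(sel, attr)) < envelope

    @pytest.mark.parametrize("dataset", ["data1", "data2"])
    def test_jensen_ordering_on_fixtures(self, dataset, zero_priors):
        s = load_fixture(dataset)
        ws = _TKWorkspace(s, zero_priors)
        sel = tk_estimate(s, zero_priors, LossSpec("SEL"), workspace=ws, with_sd=False)
        plus = tk_estimate(s, zero_priors, LossSpec("LINEX", 0.7),
                           workspace=ws, with_sd=False)
        minus = tk_estimate(s, zero_priors, LossSpec("LINEX", -0.7),
                            workspace=ws, with_sd=False)
        for attr in ("theta", "p"):
            # ordering asserted up to the approximation's resolution: when
            # k*alpha is tiny (data1 theta ~ 1e-3) the Jensen gap k*Var/2
            # sits below the O(1/n^2) method error
            slack = 1e-5 * (1.0 + abs(getattr(sel, attr)))
            assert getattr(plus, attr) <= getattr(sel, attr) + slack
            assert getattr(sel, attr) <= getattr(minus, attr) + slack

    def test_posterior_sd_close_to_oracle(self, sample_n50, flat_priors):
        est = tk_estimate(sample_n50, flat_priors, LossSpec("SEL"))
        m1 = oracle_expectation(sample_n50, flat_priors, lambda th, p: p).value
        m2 = oracle_expectation(sample_n50, flat_priors, lambda th, p: p**2).value
        assert est.sd[1] == pytest.approx(np.sqrt(m2 - m1**2), rel=0.15)


def test_joint_product_approximates_product_expectation(sample_n50, flat_priors):
    joint = tk_joint_product_expectation(sample_n50, flat_priors)
    exact = oracle_expectation(sample_n50, flat_priors, lambda th, p: th * p).value
    assert joint == pytest.approx(exact, rel=1e-2)
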