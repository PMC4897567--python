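import numpy as np
import pytest

from gebayes import (
    GEParams,
    GammaPriors,
    SurvivalSample,
    calibrate_censoring_bound,
    generate_censored_sample,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def flat_priors():
    """b = d = 1, a = c = 0: the prior contributes nothing anywhere."""
    return GammaPriors(a=0.0, b=1.0, c=0.0, d=1.0)


@pytest.fixture(scope="session")
def zero_priors():
    """The improper all-zero setting, prior proportional to 1/(theta p)."""
    return GammaPriors()


def make_censored_sample(n, theta=1.0, p=2.0, censor_fraction=0.25, seed=0):
    truth = GEParams(theta, p)
    bound = calibrate_censoring_bound(truth, censor_fraction)
    rng = np.random.default_rng(seed)
    return generate_censored_sample(truth, n, bound, rng)


@pytest.fixture(scope="session")
def sample_n50():
    """Seeded GE(1, 2) sample of size 50 with 25% expected censoring."""
    return make_censored_sample(50, seed=42)


@pytest.fixture(scope="session")
def sample_n20():
    return make_censored_sample(20, theta=1.3, p=2.4, seed=7)


@pytest.fixture
def tiny_sample():
    """One event at t=1, one censored at t=2."""
    return SurvivalSample(np.array([1.0, 2.0]), np.array([1, 0]))
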