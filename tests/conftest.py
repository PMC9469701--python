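"""Shared fixtures: the reference regimen, truths, and one reusable fit."""

import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True)
_hsettings.load_profile("deterministic")

from pmxbayes import (
    TwoCptParams,
    build_tutorial_regimen,
    sample_hmc,
    simulate_dataset,
)
from pmxbayes.models import FKParams
from pmxbayes.paramspace import init_from_prior
from pmxbayes.posterior import build_pk_posterior

TRUTH = TwoCptParams(CL=10.0, Q=15.0, Vcent=35.0, Vperi=105.0, ka=2.0)
TRUTH_SIGMA = 0.2
FK_TRUTH = FKParams(mtt=125.0, circ0=5.0, alpha=3.0e-3, gamma=0.17)


@pytest.fixture(scope="session")
def tutorial_schedule():
    return build_tutorial_regimen()


@pytest.fixture(scope="session")
def expanded_schedule():
    return build_tutorial_regimen(expanded=True)


@pytest.fixture(scope="session")
def truth():
    return TRUTH


@pytest.fixture(scope="session")
def fk_truth():
    return FK_TRUTH


@pytest.fixture(scope="session")
def simulated_data(tutorial_schedule):
    return simulate_dataset(tutorial_schedule, TRUTH, sigma=TRUTH_SIGMA, seed=20260927)


@pytest.fixture(scope="session")
def twocpt_fit(simulated_data):
    """One short two-compartment fit reused by checking/comparison tests."""
    post = build_pk_posterior(simulated_data, model="twocpt")
    inits = init_from_prior(post.space, 2, seed=101)
    return sample_hmc(
        post, n_chains=2, inits=inits, n_warmup=400, n_sampling=400, seed=101
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
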