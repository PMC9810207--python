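import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bammi import GibbsConfig, PriorSpec, build_designs, planted_rank_trial, simulate_trial

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_trial():
    """One default simulated trial (20 x 9 x 3) plus its generating effects."""
    return simulate_trial(12345)


@pytest.fixture(scope="session")
def default_designs(default_trial):
    data, _ = default_trial
    return build_designs(data)


@pytest.fixture(scope="session")
def planted2_trial():
    """Trial with an exactly rank-2 planted interaction (lambda = 13, 8)."""
    return planted_rank_trial(7, lambdas=(13.0, 8.0))


@pytest.fixture(scope="session")
def additive_trial():
    """Trial with no interaction at all."""
    return simulate_trial(11, var_unstable=0.0, var_stable=0.0)


@pytest.fixture(scope="session")
def default_gibbs_fit(default_trial, default_designs):
    """A medium-length flat-prior fit at t=2 on the default trial, reused by
    invariant, diagnostic and summary tests."""
    from bammi import run_gibbs

    data, _ = default_trial
    cfg = GibbsConfig(iterations=2500, burn_in=500, seed=42, t_fixed=2, check_fraction=0.0)
    return run_gibbs(data, default_designs, PriorSpec("bammi"), cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
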