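import numpy as np
import pytest

from ralesim import SimParams, evolve
from ralesim import panels as pn


@pytest.fixture(scope="session")
def tiny_pop():
    """Small equilibrated population with causative variation (lambda=0.1)."""
    params = SimParams.from_scaled(
        N=100, theta=20, theta_d=2, rho=20, lambda_effect=0.1,
        n_generations=800, seed=1234,
    )
    return evolve(params)


@pytest.fixture(scope="session")
def null_pop():
    """Small equilibrated population with phenotypically silent causative
    class (lambda=0)."""
    params = SimParams.from_scaled(
        N=100, theta=20, theta_d=2, rho=20, lambda_effect=0.0,
        n_generations=800, seed=4321,
    )
    return evolve(params)


@pytest.fixture(scope="session")
def tiny_panel(tiny_pop):
    rng = np.random.default_rng(99)
    return pn.draw_case_control(tiny_pop, 15, 15, rng)


@pytest.fixture(scope="session")
def null_panel(null_pop):
    rng = np.random.default_rng(98)
    return pn.draw_case_control(null_pop, 15, 15, rng)
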