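import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import evofit as ef

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid101():
    return ef.StrategyGrid.uniform(101)


@pytest.fixture(scope="session")
def grid201():
    return ef.StrategyGrid.uniform(201)


@pytest.fixture(scope="session")
def example2_field(grid201):
    """Time-dependent reproduction run (k = v t e^{-vt}, rho0 = 1) to t = 50."""
    model = ef.time_dependent_reproduction_model(grid201)
    return ef.simulate_nonlocal_logistic(model, 50.0, n_out=201)


@pytest.fixture(scope="session")
def example3_field(grid101):
    """Linear trade-off run (k = 1+v, r = 1, rho0 = 1) to t = 500."""
    model = ef.tradeoff_model(grid101, k=lambda v: 1.0 + v)
    return ef.simulate_nonlocal_logistic(model, 500.0, n_out=401)


@pytest.fixture(scope="session")
def lq_eta_field(grid101):
    """Linear-quadratic trade-off run in generalised density eta = rho^(1/r)."""
    from evofit.synthetic import tradeoff_family

    fam = tradeoff_family("linear-quadratic")
    model = ef.tradeoff_model(grid101, k=fam.k, r=fam.r)
    rho = ef.simulate_nonlocal_logistic(model, 500.0, n_out=401)
    return ef.transform_density(rho, fam.r)
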