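import numpy as np
import pytest

import insilico as isd


@pytest.fixture(scope="session")
def truth() -> isd.RateConstants:
    return isd.RateConstants(*isd.K_TRUE_50C)


@pytest.fixture(scope="session")
def conditions():
    """The four residence-time experiments at the default feed level."""
    return isd.default_conditions()


@pytest.fixture(scope="session")
def ideal_series(conditions, truth):
    """Noiseless series for the four default experiments (computed once)."""
    return tuple(isd.simulate_reactor(spec, truth) for spec in conditions)


@pytest.fixture(scope="session")
def noiseless_experiments(conditions, ideal_series):
    return isd.ExperimentSet(tuple(zip(conditions, ideal_series)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
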