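import numpy as np
import pytest

from evppi import (DecisionContext, EconomicConstants, default_posterior_spec,
                   sample_posterior)

SEED = 20140121


@pytest.fixture(scope="session")
def spec():
    return default_posterior_spec()


@pytest.fixture(scope="session")
def econ():
    return EconomicConstants()


@pytest.fixture(scope="session")
def ctx():
    return DecisionContext(wtp=250.0)


@pytest.fixture(scope="session")
def samples_small(spec):
    """20k joint draws: enough for structural checks, cheap to rebuild."""
    return sample_posterior(spec, 20_000, seed=SEED)


@pytest.fixture(scope="session")
def samples_medium(spec):
    """200k joint draws for moment-recovery and cross-method checks."""
    return sample_posterior(spec, 200_000, seed=SEED)


@pytest.fixture(scope="session")
def samples_1m(spec):
    """The headline-analysis sample size, shared across acceptance checks."""
    return sample_posterior(spec, 1_000_000, seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
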