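import pytest

from bgdcm import canonical_scenario, default_priors
from bgdcm.network import DCMParams


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def scenario():
    return canonical_scenario()


@pytest.fixture(scope="session")
def mean_params(scenario):
    """Ground-truth group-mean parameters of the canonical scenario."""
    return DCMParams.from_vector(scenario.mean_vector())


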