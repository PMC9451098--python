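import numpy as np
import pytest

from metarelapse.core import GompertzParams
from metarelapse.population import PopulationParams


@pytest.fixture(scope="session")
def base_pop() -> PopulationParams:
    """Base synthetic-study population (alpha_pop 0.005, mu_pop 7e-12)."""
    return PopulationParams()


@pytest.fixture(scope="session")
def growth() -> GompertzParams:
    return GompertzParams.from_alpha(0.005)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)


def random_growth_params(rng, n):
    """Random Gompertz parameter draws spanning the clinically relevant range."""
    alphas = np.exp(rng.uniform(np.log(5e-4), np.log(0.2), n))
    return [GompertzParams.from_alpha(a) for a in alphas]
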