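import numpy as np
import pytest
from hypothesis import settings

import stratamiss as sm

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_pop() -> sm.Population:
    """A 20,000-unit population under the default generative model."""
    return sm.generate_population(sm.PopulationConfig(N=20_000), np.random.default_rng(42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
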