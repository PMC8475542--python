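import numpy as np
import pytest

from condock.synthetic import ScenarioSpec, generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """One default scenario shared by read-only tests."""
    return generate_scenario(ScenarioSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
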