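import numpy as np
import pytest

from graspmap import GridSpec, SessionConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """One 45-trial session with one neuron of every archetype."""
    from graspmap.synthgen import ARCHETYPES

    mix = {name: 1 for name in ARCHETYPES}
    return generate_session(mix, SessionConfig(n_trials=45, seed=11))


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
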