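import numpy as np
import pytest

from epicrosstalk.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A small, fully planted synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def strong_cohort():
    """Well-separated cluster structure (large effect, low noise)."""
    return simulate_cohort(
        SimulationConfig(seed=7, effect_size=3.0, noise_sd=0.5, n_samples=120)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
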