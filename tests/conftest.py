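import pytest

from mmiburden import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """One fully realised synthetic cohort shared across the suite."""
    return simulate(SimulationConfig(n_mothers=600, seed=7))
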