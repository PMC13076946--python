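import numpy as np
import pytest

from geiprs.simulate import SimulationConfig, scenario_weights, simulate_study


@pytest.fixture(scope="session")
def small_truth():
    """A small two-subpopulation simulation shared across tests."""
    cfg = SimulationConfig(
        n_samples=600,
        n_variants=60,
        n_blocks=6,
        n_causal_main=6,
        n_causal_gei=6,
        component_weights=scenario_weights("moderate", "moderate"),
        n_replicates=3,
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
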