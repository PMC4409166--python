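import pytest

from ecoevo.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def mixed_tables():
    """One simulated experiment under the default mixed scenario."""
    return simulate_experiment(SimulationConfig(scenario="mixed", seed=101, include_transfers=False))


@pytest.fixture(scope="session")
def exact_additive_tables():
    """Noise-free, purely additive experiment: A equals the sum of
    monoculture yields exactly, nothing changes over time."""
    config = SimulationConfig(
        scenario="neutral_additive",
        seed=7,
        noise_sd=0.0,
        microcosm_sd=0.0,
        od_reading_sd=0.0,
        include_transfers=False,
    )
    return simulate_experiment(config)
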