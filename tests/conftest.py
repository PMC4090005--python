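"""Shared fixtures: one small simulated dataset reused across test modules."""

import pytest

from chromdiverge import simulate as sim


@pytest.fixture(scope="session")
def small_config() -> sim.SimulationConfig:
    return sim.SimulationConfig(
        n_genes=300,
        n_chroms=2,
        reads_per_sample=100_000,
        rna_depth=300_000,
        fragment_length=125,
        n_conditions=60,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sim.SimulatedDataset:
    return sim.simulate_dataset(small_config)
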