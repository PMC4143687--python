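"""Shared fixtures: small simulated datasets and a fitted chain reused across tests."""

import numpy as np
import pytest

from pleiolvm import (
    MCMCConfig,
    ModelSpec,
    PriorSpec,
    SimConfig,
    run_chain,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def tiny_config():
    """3 families x 3-5 members, two continuous phenotypes."""
    return SimConfig(n_families=3, family_size_range=(3, 5), seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_fit(tiny_dataset, tiny_config):
    return tiny_dataset.design(tiny_config.model_spec())


@pytest.fixture(scope="session")
def mixed_config():
    """Small design with one continuous and one binary phenotype."""
    return SimConfig(
        n_families=3,
        family_size_range=(3, 4),
        seed=11,
        continuous_names=("sbp",),
        binary_names=("htn",),
    )


@pytest.fixture(scope="session")
def mixed_dataset(mixed_config):
    return simulate_dataset(mixed_config)


@pytest.fixture(scope="session")
def mixed_fit(mixed_dataset, mixed_config):
    return mixed_dataset.design(mixed_config.model_spec())


@pytest.fixture(scope="session")
def small_samples(tiny_dataset, tiny_config):
    """A short but real chain on the tiny dataset, shared by summary tests."""
    return run_chain(
        tiny_dataset,
        tiny_config.model_spec(),
        PriorSpec(),
        MCMCConfig(n_iter=900, burn_in=300, thin=2, seed=3),
    )
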