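"""Shared fixtures: small synthetic study datasets, generated at test time."""
import numpy as np
import pytest

from mesofish.synth import (SynthConfig, generate_community,
                            generate_reference_library, generate_traits)


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=11)


@pytest.fixture(scope="session")
def library(default_config):
    """(records, taxonomy, truth) for the default reference library."""
    return generate_reference_library(default_config)


@pytest.fixture(scope="session")
def community(default_config, library):
    """(tables, sample_to_island, truth) for the default two-island study."""
    _, _, truth = library
    tables, sample_to_island = generate_community(default_config, truth)
    return tables, sample_to_island, truth


@pytest.fixture(scope="session")
def trait_table(community, library):
    _, _, truth = library
    return generate_traits(truth)


def family_of_species(species: str) -> str:
    return species.rsplit("-", 2)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
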