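import numpy as np
import pytest

from chromarch.synthdata import FamilySpec, SimParams, gen_genome_layout


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Desk-scale parameter set used by most simulation-driven tests."""
    return SimParams(seed=0, n_species=4)


@pytest.fixture(scope="session")
def small_layout(small_params):
    return gen_genome_layout(small_params)


@pytest.fixture(scope="session")
def one_species_satellites(small_params, small_layout):
    from chromarch.synthdata import gen_satellite_dataset

    return gen_satellite_dataset(small_params, small_layout, species=["S01"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
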