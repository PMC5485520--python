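import numpy as np
import pytest

from emmir import simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170606)


@pytest.fixture(scope="session")
def planted():
    """A small genome with 12 planted hairpins and uniform abundance."""
    genome = simulate.generate_genome(20_000, gc=0.45, seed=11)
    genome, truth = simulate.plant_hairpins(genome, 12, seed=12)
    truth.base_abundance = {k: 1.0 for k in truth.base_abundance}
    return genome, truth


@pytest.fixture(scope="session")
def ncrna_refs():
    return simulate.make_ncrna_references(seed=13)
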