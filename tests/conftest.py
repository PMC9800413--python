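import numpy as np
import pytest

from petag.genome import Genome
from petag.simulate import SimulationConfig, example_target


@pytest.fixture(scope="session")
def toy():
    """(pegRNA, context block, protospacer offset) for the built-in target."""
    return example_target()


@pytest.fixture(scope="session")
def pegrna(toy):
    return toy[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_genome(rng, n, name="chr1") -> Genome:
    return Genome({name: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))})


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale simulation settings shared by cross-module tests."""
    return SimulationConfig(
        seed=7, genome_length=12_000, n_offtargets=10, reads_per_site=20,
        site_spacing=500, error_rate=0.0,
    )
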