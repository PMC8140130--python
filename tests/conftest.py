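import numpy as np
import pytest

from dmrcompare.fixtures import FixtureConfig, generate_genome, plant_dmrs


def small_fixture_config(seed: int = 11) -> FixtureConfig:
    """A scaled-down cohort (3 x 1 Mb) for fast unit tests."""
    return FixtureConfig(
        seed=seed,
        chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000},
        n_genes=80,
        n_random_islands=40,
        n_enhancer_loci=120,
        te_subfamilies=[("SYNL1", 80, 350), ("SYNS1", 70, 250), ("MERX", 60, 400)],
        n_probes=800,
        n_hyper={"A": 300, "B": 200},
        n_hypo={"A": 150, "B": 100},
    )


@pytest.fixture(scope="session")
def small_config():
    return small_fixture_config()


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_planted(small_config, small_genome):
    return plant_dmrs(small_config, small_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
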