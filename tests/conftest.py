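import numpy as np
import pytest

from caprapop.synthetic_data import SimConfig, population_map, simulate_genotypes


@pytest.fixture(scope="session")
def small_sim():
    """A small three-population mosaic simulation shared across tests."""
    cfg = SimConfig(
        pop_sizes={"Black": 10, "Draa": 10, "Northern": 6},
        chrom_lengths={"chr1": 1_000_000},
        n_sites=3000,
        seed=123,
    )
    matrix, truth = simulate_genotypes(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_pop_map(small_sim):
    cfg, _, _ = small_sim
    return population_map(cfg)
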