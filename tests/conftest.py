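import numpy as np
import pytest

from admixsib import (
    GeneticMap,
    default_map,
    simulate_ancestral_freqs,
    simulate_genotypes,
    simulate_population,
)


@pytest.fixture(scope="session")
def gmap_small() -> GeneticMap:
    """Four 1-Morgan chromosomes: enough recombination to be interesting, fast."""
    return GeneticMap(tuple((str(i + 1), 1.0) for i in range(4)))


@pytest.fixture(scope="session")
def gmap_full() -> GeneticMap:
    return default_map()


@pytest.fixture(scope="session")
def small_population(gmap_full):
    """30 default-composition families on the full map, with genotypes."""
    pop = simulate_population(30, seed=11)
    freqs = simulate_ancestral_freqs(1500, 0.2, pop.gmap, seed=12)
    G = simulate_genotypes(pop, freqs, seed=13)
    return pop, freqs, G
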