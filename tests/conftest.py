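import pytest

from metapan.catalog import ani_matrix
from metapan.pangenome import build_pangenome
from metapan.simulate import SimulationConfig, simulate_catalog


@pytest.fixture(scope="session")
def sim_catalog():
    """Default synthetic catalog: 3 species x 4 genomes, ~12 kb each."""
    return simulate_catalog(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_pangenome(sim_catalog):
    """Pangenome built on the full (pre-dereplication) synthetic catalog."""
    _, genes, _ = sim_catalog
    return build_pangenome(genes)


@pytest.fixture(scope="session")
def small_ani_catalog():
    """Compact catalog (3 species x 2 genomes, 6 kb) with its full ANI matrix;
    small enough that all-pairs fragment alignment stays fast."""
    cfg = SimulationConfig(seed=2, genomes_per_species=2, genome_len=6000)
    genomes, genes, truth = simulate_catalog(cfg)
    ani = ani_matrix(genomes)
    return cfg, genomes, truth, ani
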