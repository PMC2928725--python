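import numpy as np
import pytest

from epiqtl.coalsim import SimConfig, assemble_diploids, simulate_panel


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome: 3 chromosomes x 20 markers, QTLs on chr1/chr2."""
    return SimConfig(
        n_individuals=60,
        n_chromosomes=3,
        markers_per_chromosome=20,
        qtl_positions=((0, 9), (1, 9)),
        maf_window=(0.2, 0.3),
        genealogy_seed=11,
        mutation_seed=12,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def small_genotypes(small_panel):
    return assemble_diploids(small_panel)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def all_nine_classes_genotypes(n_per_cell: int) -> np.ndarray:
    """(9*n_per_cell, 2) genotype matrix with every two-locus class filled."""
    cells = [(i, j) for i in range(3) for j in range(3)]
    return np.repeat(np.array(cells, dtype=np.uint8), n_per_cell, axis=0)
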