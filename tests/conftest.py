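import numpy as np
import pytest

from fingertax.fingerprint_index import PhyloTree, build_index
from fingertax.synthetic_community import SimulationConfig, simulate_tree_and_genomes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_taxa=6, genome_length=6000, reads_per_sample=3000,
                            gene_length=600, seed=11)


@pytest.fixture(scope="session")
def small_refs(small_config):
    return simulate_tree_and_genomes(small_config)


@pytest.fixture(scope="session")
def small_index(small_refs):
    tree, genomes = small_refs
    return build_index(genomes, tree, k=21)


@pytest.fixture(scope="session")
def four_leaf_tree():
    return PhyloTree.from_newick("((A,B),(C,D));")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
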