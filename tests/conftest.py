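import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phamlin import SimConfig, simulate_pangenome
from phamlin.synthetic_data import proteins_from_genomes


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated pangenome shared across tests (seed fixed)."""
    config = SimConfig(seed=42, n_clusters=3, cluster_size_range=(3, 4),
                       n_singletons=1, genes_per_genome=(10, 14))
    genomes, truth = simulate_pangenome(config)
    return genomes, truth


@pytest.fixture(scope="session")
def small_sim_proteins(small_sim):
    genomes, _ = small_sim
    return proteins_from_genomes(genomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
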