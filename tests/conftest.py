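import numpy as np
import pytest

from apa3t import Genome, SimConfig, generate_genome, generate_reads


def make_genome(**seqs: str) -> Genome:
    return Genome(seqs)


@pytest.fixture(scope="session")
def small_sim():
    """A small in-memory synthetic study with jitter and priming traps."""
    config = SimConfig(
        n_genes=40,
        reads_per_gene=120.0,
        n_priming_traps=8,
        seed=7,
    )
    genome, genes, known, truth = generate_genome(config)
    reads = generate_reads(genome, genes, truth, config)
    return config, genome, genes, known, truth, reads


@pytest.fixture(scope="session")
def clean_sim():
    """Jitter-free, trap-free study: read ends sit exactly on true sites."""
    config = SimConfig(
        n_genes=30,
        reads_per_gene=100.0,
        jitter_sd=0.0,
        n_priming_traps=0,
        seed=11,
    )
    genome, genes, known, truth = generate_genome(config)
    reads = generate_reads(genome, genes, truth, config)
    return config, genome, genes, known, truth, reads


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
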