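import numpy as np
import pytest

from nanomethqc import synthetic
from nanomethqc.core_io import GenomeSequence


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale-but-quick study conditions for unit tests."""
    return synthetic.SimulationConfig(
        seed=11,
        n_contigs=2,
        contig_length=30_000,
        n_reads=300,
        mean_read_length=2000,
        min_read_length=200,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(genomes, truth, reads) simulated once for the whole session."""
    genomes, truth = synthetic.simulate_genome(small_config)
    synthetic.simulate_methylome(genomes, small_config, truth)
    reads = synthetic.simulate_ont_reads(genomes, truth, small_config)
    return genomes, truth, reads


@pytest.fixture(scope="session")
def ref_map(small_dataset):
    genomes, _, _ = small_dataset
    return {g.name: g for g in genomes}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_contig(name: str, sequence: str) -> GenomeSequence:
    return GenomeSequence(name, sequence.upper())
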