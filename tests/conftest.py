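import numpy as np
import pytest

from hetasm.simulate import (
    LibrarySpec,
    SimConfig,
    simulate_diploid_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_truth():
    """A 50 kbp diploid genome with a hemizygous chromosome."""
    cfg = SimConfig(
        genome_length=50_000,
        heterozygosity=0.005,
        hemizygous_fraction=0.2,
        n_chromosomes=2,
        seed=11,
    )
    return simulate_diploid_genome(cfg)


@pytest.fixture(scope="session")
def small_pe_pairs(small_truth):
    lib = LibrarySpec(kind="paired_end", fragment_mean=400, fragment_sd=40, coverage=40, name="pe")
    return simulate_reads(small_truth, lib, seed=5)


@pytest.fixture(scope="session")
def small_assembly(small_pe_pairs):
    from hetasm.pipeline import assemble

    reads = [r.seq for pair in small_pe_pairs for r in pair]
    contigs, records = assemble(reads, k=25)
    return contigs, records


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
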