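import numpy as np
import pytest

from virescue.genome import Chromosome, CrossDesign, GenomeModel, SeqModel, default_genome
from virescue.pipeline import simulate_variant_table


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture(scope="session")
def tiny_genome():
    """One short chromosome with the causal locus in the middle; cheap to
    simulate in bulk."""
    return GenomeModel(
        chromosomes=(Chromosome("chr1", 1_000_000, 50.0),),
        marker_spacing_bp=200_000,
        causal_chrom="chr1",
        causal_pos=600_000,
    )


@pytest.fixture(scope="session")
def default_sim(genome):
    """One default-condition simulation (seed 1): population, pools, table."""
    return simulate_variant_table(genome, CrossDesign(), SeqModel(), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
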