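import numpy as np
import pytest

from episcore.intervals import GeneModel, GenomicInterval, IntervalSet
from episcore.synthetic_data import SimConfig, make_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    """A compact deterministic genome shared across tests."""
    return make_genome(SimConfig(seed=7, n_genes=60, n_chroms=1))


@pytest.fixture
def two_gene_models():
    """One plus- and one minus-strand gene on chr1, far apart."""
    return [
        GeneModel("GP", "chr1", 1, 100_000, 120_000),
        GeneModel("GM", "chr1", -1, 500_000, 520_000),
    ]


def iset(raw, sample="s", mark="custom"):
    """Build an IntervalSet from (chrom, start, end) tuples."""
    return IntervalSet([GenomicInterval(c, s, e) for c, s, e in raw], sample, mark)
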