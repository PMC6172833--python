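import numpy as np
import pytest

from butlrkit import ChromTable, make_bin_index


@pytest.fixture
def chrom_table() -> ChromTable:
    return ChromTable([("chr1", 2_400_000), ("chr2", 1_600_000)])


@pytest.fixture
def bin_index(chrom_table):
    return make_bin_index(chrom_table, 40_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
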