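import numpy as np
import pytest

from hicdelta.matrix import ContactMap, GenomeBinning


def symmetric_random(n: int, rng: np.random.Generator, scale: float = 50.0):
    """Random symmetric nonnegative integer matrix."""
    m = rng.poisson(scale, size=(n, n)).astype(float)
    m = np.triu(m)
    return m + np.triu(m, 1).T


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_binning():
    # two chromosomes, 3 Mb + 2 Mb at 1 Mb bins -> 5 bins
    return GenomeBinning((("chr1", 3_000_000), ("chr2", 2_000_000)), 1_000_000)


@pytest.fixture
def random_map_pair(rng):
    """Two random 50-bin maps over two chromosomes (30 + 20 bins)."""
    binning = GenomeBinning.from_bin_counts([30, 20], bin_size=1_000_000)
    a = ContactMap(binning, symmetric_random(50, rng))
    b = ContactMap(binning, symmetric_random(50, rng))
    return a, b
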