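import numpy as np
import pytest

from diatomsim import make_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layout():
    """Shared 100 kb chromosome with 5 microsatellites."""
    return make_layout(layout_seed=1, chrom_len=100_000)


@pytest.fixture(scope="session")
def two_locus_layout():
    """Tiny 2-locus layout for exhaustive meiosis checks."""
    return make_layout(layout_seed=3, chrom_len=10_000, n_loci=2)
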