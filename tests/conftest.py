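import numpy as np
import pytest

from cnvseg import simulate


@pytest.fixture
def small_layout():
    """One chromosome, 1000 probes at the default 2509-bp spacing."""
    return simulate.make_layout(1, 2_509_000, 2509, seed=0)


@pytest.fixture
def two_chrom_layout():
    """Two chromosomes x 300 probes; cheap enough for per-test pipelines."""
    return simulate.make_layout(2, 300 * 2509, 2509, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
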