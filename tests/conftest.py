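import numpy as np
import pytest

from nucleofoot import synthetic


@pytest.fixture(scope="session")
def profiles():
    """Default synthetic healthy/tumor M-profiles."""
    return synthetic.make_m_profiles()


@pytest.fixture(scope="session")
def small_annotation():
    """Compact bin grid (2 chromosomes x 120 bins) for fast CNA tests."""
    return synthetic.make_bin_annotation(
        n_chroms=2, bins_per_chrom=120, seed=1
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
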