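import numpy as np
import pytest

from abrwarp import TimeWindow, make_template, simulate_dataset


@pytest.fixture(scope="session")
def window():
    """The standard warping window: 0-12 ms sampled at 16.384 kHz."""
    return TimeWindow.from_fs(0.0, 12.0, 16384.0)


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def noiseless_sim():
    """10 noiseless subjects under random warps of magnitude 0.3."""
    return simulate_dataset(
        n_subjects=10, warp_magnitude=0.3, dsnr_grid=[0.0], seed=0,
        noise_rms=0.0, with_replicates=False,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
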