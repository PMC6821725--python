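import numpy as np
import pytest

from rhodokit import datasets as d
from rhodokit import synthetic as syn


@pytest.fixture(scope="session")
def scheme():
    return syn.olpvr2_scheme()


@pytest.fixture(scope="session")
def peak_signal(scheme):
    return syn.photocycle_peak_signal(scheme)


@pytest.fixture(scope="session")
def noiseless_dataset(scheme):
    return syn.gen_photocycle_dataset(scheme)


@pytest.fixture(scope="session")
def snr100_dataset(scheme, peak_signal):
    """Default-grid dataset at single-flash SNR 100 with 25-pulse averaging."""
    return syn.gen_photocycle_dataset(
        scheme, noise=d.NoiseSpec(peak_signal / 100.0, seed=2024,
                                  n_averages=25))


@pytest.fixture(scope="session")
def pentamer():
    return syn.gen_ideal_pentamer(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
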