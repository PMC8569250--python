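import numpy as np
import pytest

from neurocoh.montage import BandSet, ChannelMontage, ClusterPair, Recording
from neurocoh.preprocess import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_montage():
    return ChannelMontage(("C3", "C4", "Cz", "Pz"))


@pytest.fixture
def pair_c3c4():
    return ClusterPair(left=frozenset({"C3"}), right=frozenset({"C4"}))


@pytest.fixture
def noise_recording(rng, small_montage):
    """10 s of 4-channel white noise at 1000 Hz."""
    data = rng.standard_normal((4, 10_000))
    return Recording(data=data, fs=1000.0, montage=small_montage)


@pytest.fixture
def noise_epochs(noise_recording):
    from neurocoh.preprocess import epoch

    return epoch(noise_recording, 2000.0)


@pytest.fixture
def two_band_set():
    return BandSet((("delta", (1.0, 4.0)), ("theta", (4.0, 8.0))))


def make_epochset(data_3d, fs, montage):
    n_samples = data_3d.shape[2]
    return EpochSet(epochs=data_3d, fs=fs, epoch_ms=1000.0 * n_samples / fs, montage=montage)
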