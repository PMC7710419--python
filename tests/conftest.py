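import numpy as np
import pytest

from eegnet.recording import EpochSet, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_recording(data, fs=256.0):
    n_ch = data.shape[0]
    labels = tuple(f"ch{i}" for i in range(n_ch))
    return Recording(data=np.asarray(data, float), fs=fs, channel_labels=labels)


def make_epochs(data, fs=256.0, epoch_length=None):
    """Wrap an (n_epochs, n_channels, n_samples) array as an EpochSet."""
    data = np.asarray(data, float)
    if epoch_length is None:
        epoch_length = data.shape[-1] / fs
    return EpochSet(
        epochs=data,
        fs=fs,
        epoch_length=epoch_length,
        channel_labels=tuple(f"ch{i}" for i in range(data.shape[1])),
        retained_mask=np.ones(data.shape[0], dtype=bool),
    )


@pytest.fixture
def white_epochs(rng):
    """50 six-second two-channel white-noise epochs at 256 Hz."""
    return make_epochs(rng.standard_normal((50, 2, 1536)))
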