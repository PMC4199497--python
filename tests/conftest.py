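import numpy as np
import pytest

from eegspan import EpochedRecording, Montage, generate_montage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def montage91():
    return generate_montage(91, seed=0)


@pytest.fixture
def montage_small():
    return generate_montage(12, seed=3)


def make_recording(data, fs=250.0, labels=None, epoch_length=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"E{i + 1}" for i in range(data.shape[0]))
    return EpochedRecording(data=data, sampling_rate=fs, labels=labels,
                            epoch_length=epoch_length)


@pytest.fixture
def tone_recording():
    """60 epochs × 10 s of a pure 10 Hz unit sinusoid on 2 channels."""
    fs, n_epochs, length = 250.0, 60, 10.0
    t = np.arange(int(fs * length)) / fs
    tone = np.sin(2 * np.pi * 10.0 * t)
    data = np.tile(tone, (2, n_epochs, 1))
    return make_recording(data, fs, epoch_length=length)
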