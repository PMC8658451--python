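import numpy as np
import pytest

from eegmst.core import EpochedRecording, get_band


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def theta():
    return get_band("theta")


@pytest.fixture
def alpha():
    return get_band("alpha")


def make_recording(
    data: np.ndarray,
    fs: float = 1024.0,
    subject_id: str = "s01",
    group: str = "typical",
    condition: str = "baseline",
    channels=None,
) -> EpochedRecording:
    """Wrap raw (n_epochs, n_channels, n_samples) data as a recording."""
    data = np.asarray(data, dtype=float)
    if channels is None:
        channels = tuple(f"ch{i:02d}" for i in range(data.shape[1]))
    return EpochedRecording(
        subject_id=subject_id,
        group=group,
        condition=condition,
        fs=fs,
        channels=channels,
        epochs=data,
    )


@pytest.fixture
def small_recording(rng):
    """3 channels, 2 epochs, 1 s at 256 Hz of white noise."""
    return make_recording(rng.standard_normal((2, 3, 256)), fs=256.0)


@pytest.fixture
def sine_recording():
    """Single-channel 4-s, 1024 Hz recording of a 6 Hz sinusoid."""
    fs = 1024.0
    t = np.arange(0, 4, 1 / fs)
    return make_recording(np.cos(2 * np.pi * 6 * t)[None, None, :], fs=fs)
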