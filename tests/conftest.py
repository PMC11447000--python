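import numpy as np
import pytest

from ephyskit.recording import ACTIVITY, EEG, EMG, Channel, TimeSeriesRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(eeg, fs=500.0, emg=None, activity=None, act_fs=200.0):
    """Assemble a recording from raw channel arrays."""
    channels = [Channel(EEG, np.asarray(eeg, dtype=float), fs)]
    if emg is not None:
        channels.append(Channel(EMG, np.asarray(emg, dtype=float), fs))
    if activity is not None:
        channels.append(Channel(ACTIVITY, np.asarray(activity, dtype=float), act_fs))
    return TimeSeriesRecording(channels)


@pytest.fixture
def quiet_recording(rng):
    """10 minutes of low-amplitude (10 µV sd) EEG noise with flat EMG/activity."""
    n = 500 * 600
    return make_recording(
        rng.normal(0, 10, n),
        emg=rng.normal(0, 10, n),
        activity=np.zeros(200 * 600),
    )
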