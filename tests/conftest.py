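import numpy as np
import pytest

from gaitmoment.signal_io import ChannelSpec, RecordingBundle, SignalRecording
from gaitmoment.preprocessing import WindowSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(samples, rate=200.0, kinds=None, names=None, **kw):
    samples = np.asarray(samples, dtype=np.float64)
    n_ch = samples.shape[1]
    kinds = kinds or ["emg"] * n_ch
    names = names or [f"ch{i}" for i in range(n_ch)]
    channels = [ChannelSpec(n, k) for n, k in zip(names, kinds)]
    return SignalRecording(channels=channels, samples=samples, rate=rate, **kw)


@pytest.fixture
def small_bundle(rng):
    """Aligned bundle: 2 predictor channels, 1 moment channel, 100 samples."""
    pred = make_recording(rng.standard_normal((100, 2)), kinds=["emg", "angle"])
    tgt = make_recording(
        rng.standard_normal((100, 1)), kinds=["moment"], names=["m0"]
    )
    return RecordingBundle(predictors=pred, targets=tgt, aligned=True)


@pytest.fixture
def tiny_windowset(rng):
    windows = rng.standard_normal((8, 12, 3))
    targets = rng.standard_normal((8, 2))
    return WindowSet(
        windows=windows,
        targets=targets,
        window_len=12,
        stride=1,
        rate=200.0,
        channel_names=["a", "b", "c"],
        target_names=["m0", "m1"],
    )
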