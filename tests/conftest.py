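import numpy as np
import pytest
from hypothesis import settings

from neonatal_ema.preprocessing import ELECTRODES, RecordingSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_recording(
    signal: np.ndarray,
    fs: float = 256.0,
    pma_days: int = 210,
    infant_id: str = "inf000",
    recording_id: str = "inf000_rec0",
) -> RecordingSet:
    """Wrap a (8, n) referential array in a RecordingSet."""
    return RecordingSet(
        infant_id=infant_id,
        recording_id=recording_id,
        pma_days=pma_days,
        channels=list(ELECTRODES),
        fs_native=fs,
        signal=signal,
    )


@pytest.fixture()
def sine_recording():
    """A 1-h, 256 Hz recording of distinct sinusoids per electrode."""
    fs = 256.0
    t = np.arange(int(3700 * fs)) / fs
    sig = np.stack(
        [(i + 1) * np.sin(2 * np.pi * (2 + i) * t) for i in range(8)]
    )
    return make_recording(sig, fs=fs)
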