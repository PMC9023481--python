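import numpy as np
import pytest

from pwavekit import DetectorConfig
from pwavekit.synthetic import SynthSpec, generate


@pytest.fixture
def cfg():
    return DetectorConfig()


@pytest.fixture(scope="session")
def sinus():
    """A clean 60 s, 60 bpm, 360 Hz sinus record with its truth."""
    return generate(SynthSpec(fs=360.0, duration=60.0, hr_bpm=60.0, seed=11))


def sine_record(freq, fs=360.0, duration=30.0, amp=1.0):
    from pwavekit import EcgRecord

    t = np.arange(int(duration * fs)) / fs
    return EcgRecord(amp * np.sin(2 * np.pi * freq * t), fs=fs)


def mid_amplitude(x):
    """Peak amplitude over the middle third (away from filter edges)."""
    n = len(x)
    return np.abs(x[n // 3 : 2 * n // 3]).max()
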