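import numpy as np
import pytest

from sparsespec.preprocessing import compute_spectrogram, segment_patches
from sparsespec.synthetic import SpeechLikeParams, make_speech_like_waveform


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def tone(freq_hz: float, duration_s: float = 1.0, rate: int = 16_000) -> np.ndarray:
    t = np.arange(int(duration_s * rate)) / rate
    return np.sin(2 * np.pi * freq_hz * t)


@pytest.fixture(scope="session")
def speech_patches_small():
    """A small whitenable patch set from one speech-like utterance (64 channels)."""
    wave = make_speech_like_waveform(SpeechLikeParams(duration_s=8.0, seed=7))
    spec = compute_spectrogram(wave, n_freq=64)
    ps = segment_patches(spec, patch_hop_frames=3)
    assert ps.n_patches > 100
    return ps
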