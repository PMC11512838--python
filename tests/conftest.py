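import numpy as np
import pytest

import spinsense as ss


@pytest.fixture
def constant_profile():
    return ss.RotationProfile.constant


@pytest.fixture
def noiseless_audio():
    """Noiseless pulse-train audio at a given RPM (default generator timbre)."""

    def make(rpm, seed=0, **kwargs):
        return ss.make_audio_trace(
            ss.RotationProfile.constant(rpm),
            ss.AudioModel(noise_sd=0.0),
            seed=seed,
            **kwargs,
        )

    return make


@pytest.fixture
def noiseless_mag():
    """Noiseless magnetometer pulse train at a given RPM, 50 Hz / 256 samples."""

    def make(rpm, seed=0, duration=5.12, **kwargs):
        return ss.make_magnetometer_trace(
            ss.RotationProfile.constant(rpm),
            ss.MagnetModel(noise_sd=0.0),
            duration=duration,
            seed=seed,
            **kwargs,
        )

    return make


def dense_dft_peak_hz(samples: np.ndarray, rate: float, pad: int = 100) -> float:
    """Oracle: argmax of a zero-padded (dense) magnitude spectrum, in Hz.

    Independent of the estimators' parabolic-interpolation path.
    """
    x = np.asarray(samples, float)
    x = x - x.mean()
    n = x.size
    mags = np.abs(np.fft.rfft(x, pad * n))
    mags[0] = 0.0
    return float(np.argmax(mags) * rate / (pad * n))
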