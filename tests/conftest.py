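import numpy as np
import pytest

SR = 22050


@pytest.fixture(scope="session")
def sr():
    return SR


@pytest.fixture(scope="session")
def one_second():
    return np.arange(SR) / SR


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sine(freq, duration=1.0, amplitude=1.0, sr=SR):
    t = np.arange(int(round(duration * sr))) / sr
    return amplitude * np.sin(2 * np.pi * freq * t)


def harmonic_complex(f0, duration=1.0, n_harm=10, sr=SR):
    t = np.arange(int(round(duration * sr))) / sr
    return sum((1.0 / k) * np.sin(2 * np.pi * f0 * k * t)
               for k in range(1, n_harm + 1)) / 2.93


@pytest.fixture(scope="session")
def small_waveforms():
    """Free-speech + two counting trials from one default synthetic voice."""
    from prosovoice.synthetic_voice import VoiceParams, synth_utterance

    v = VoiceParams()
    return {
        "free_speech": synth_utterance("free_speech", v, 4.0, SR, seed=7),
        "counting": [synth_utterance("counting", v, 2.0, SR, seed=8),
                     synth_utterance("counting", v, 2.0, SR, seed=9)],
    }
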