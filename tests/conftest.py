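from dataclasses import replace

import numpy as np
import pytest

from chirplab import synth


@pytest.fixture(scope="session")
def clean_song():
    """A small noiseless LD-like song with ground truth (16 kHz)."""
    spec = replace(
        synth.preset("LD-like"), n_chirps=12, seed=7, sample_rate=16000, noise_rms=0.0
    )
    return synth.synthesize_song(spec)


@pytest.fixture(scope="session")
def noisy_song():
    """The same song family with an audible noise floor (rms 0.01)."""
    spec = replace(
        synth.preset("LD-like"), n_chirps=12, seed=7, sample_rate=16000, noise_rms=0.01
    )
    return synth.synthesize_song(spec)


def truth_boundaries(truth):
    """Ground-truth (onset, offset) sample pairs for a GroundTruth."""
    fs = truth.spec.sample_rate
    return np.array([(round(a * fs), round(b * fs)) for a, b, _ in truth.syllables])
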