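import numpy as np
import pytest

from bulbarvoice.preprocess import Segment, preprocess_recording
from bulbarvoice.synthvoice import VoiceSpec, synthesize_vowel

RATE = 8820.0
SEG_LEN = 1323


@pytest.fixture(scope="session")
def vowel_segment():
    """Preprocessed 150 ms segment of a mildly perturbed type-1 vowel."""
    spec = VoiceSpec(f0=120.0, jitter_rel=0.5, shimmer_rel=1.5, hnr_db=25.0, seed=3)
    rec, _ = synthesize_vowel(spec)
    return preprocess_recording(rec)


@pytest.fixture(scope="session")
def periodic_segment():
    """Strictly periodic, noise-free vowel segment (f0 divides both rates)."""
    spec = VoiceSpec(f0=122.5, jitter_rel=0.0, shimmer_rel=0.0,
                     hnr_db=np.inf, seed=0)
    rec, _ = synthesize_vowel(spec)
    return preprocess_recording(rec)


@pytest.fixture
def tone_segment():
    def make(freq: float, n: int = SEG_LEN, rate: float = RATE) -> Segment:
        t = np.arange(n) / rate
        return Segment(samples=np.sin(2.0 * np.pi * freq * t), rate=rate)
    return make
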