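import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_detector import

from ripplepac import LfpRecording


@pytest.fixture
def tone():
    """Factory for pure-sinusoid recordings."""

    def make(freq, fs=1000.0, duration_s=10.0, amplitude=1.0, phase=0.0):
        t = np.arange(int(duration_s * fs)) / fs
        return LfpRecording(amplitude * np.sin(2 * np.pi * freq * t + phase), fs)

    return make


def random_z_envelope(rng, n_max=10000):
    """Piecewise-constant pseudo-envelope mixing sub- and supra-threshold runs.

    Run levels straddle the 3 SD detection threshold (including exact-
    threshold values, which must NOT trigger: the criterion is 'exceeding')
    and run lengths straddle the 15 ms minimum, to exercise every branch of
    the detector.
    """
    n = int(rng.integers(50, n_max))
    out = np.empty(n)
    i = 0
    levels = np.array([0.0, 1.0, 2.9, 3.0, 3.1, 4.0, 6.0, 2.0])
    while i < n:
        length = int(rng.integers(1, 40))
        out[i : i + length] = rng.choice(levels) + rng.normal(0, 0.01)
        i += length
    return out
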