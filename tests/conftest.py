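import numpy as np
import pytest

from stepstoich import PhotobleachTrace


def staircase(k: int, mu: float, frames_per_level: int = 10, pad_to: int = 50):
    """Noiseless k-step staircase trace ending at zero."""
    levels = np.repeat(np.arange(k, -1, -1) * mu, frames_per_level).astype(float)
    pad = max(0, pad_to - levels.size)
    return PhotobleachTrace(np.concatenate([levels, np.zeros(pad)]))


@pytest.fixture
def make_staircase():
    return staircase
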