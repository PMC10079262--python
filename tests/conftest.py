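import numpy as np
import pytest

from celltracks import Track, TracksDataset


@pytest.fixture
def simple_dataset():
    """Two 2D tracks of 3 observations each."""
    return TracksDataset([
        Track("a", [0, 1, 2], [[0.0, 0.0], [1.0, 0.0], [2.0, 1.0]]),
        Track("b", [0, 1, 2], [[5.0, 5.0], [5.0, 6.0], [6.0, 6.0]]),
    ])


@pytest.fixture
def straight_track():
    """Constant-speed straight 2D track: 5 steps of length 2 at dt=1."""
    pos = np.column_stack([2.0 * np.arange(6), np.zeros(6)])
    return Track("straight", np.arange(6.0), pos)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
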