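import numpy as np
import pytest

from dhsig.eeg_io import EventMatrix, Recording
from dhsig.padic import assign_codes
from dhsig.synth import SynthConfig, generate_recording
from dhsig.tree import DendroTree, build_tree


@pytest.fixture
def toy_tree() -> DendroTree:
    """Ward tree over 1-D points {0, 1, 10}: topology ((0,1),2)."""
    return build_tree(np.array([[0.0], [1.0], [10.0]]))


@pytest.fixture
def toy_coded(toy_tree):
    return assign_codes(toy_tree)


@pytest.fixture
def balanced4_tree() -> DendroTree:
    """Two tight pairs far apart: ((0,1),(2,3))."""
    return build_tree(np.array([[0.0], [1.0], [100.0], [101.0]]))


@pytest.fixture
def short_recording() -> Recording:
    return generate_recording(SynthConfig(duration=5.0, seed=7))


@pytest.fixture
def event_matrix_factory():
    """Random EventMatrix with window-major, electrode-major-within-window order."""

    def make(n_channels=19, n_windows=20, window_len=25, fs=25.0, seed=0) -> EventMatrix:
        rng = np.random.default_rng(seed)
        events = rng.standard_normal((n_channels * n_windows, window_len))
        index = [(e, w) for w in range(n_windows) for e in range(n_channels)]
        return EventMatrix(events=events, index=index, fs=fs, window_s=window_len / fs)

    return make
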