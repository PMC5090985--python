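import numpy as np
import pytest

from xlf import synthetic
from xlf.movie_io import FrameStack, ROISpec, Rect


@pytest.fixture
def small_stack() -> FrameStack:
    """Deterministic 16-frame 16x16 stack with integer-valued intensities."""
    rng = np.random.default_rng(42)
    frames = rng.integers(100, 5000, size=(16, 16, 16)).astype(np.float64)
    return FrameStack(frames=frames, frame_rate_hz=30.0)


@pytest.fixture
def small_rois() -> ROISpec:
    return ROISpec(lung_rois=[Rect(6, 12, 2, 8), Rect(6, 12, 9, 15)], background_roi=Rect(0, 4, 0, 4))


@pytest.fixture
def noiseless_scan():
    """One noiseless default scan with ground truth."""
    return synthetic.simulate_trace(synthetic.TraceSimConfig(noise_sd=0.0))
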