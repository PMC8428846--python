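import numpy as np
import pytest

from pawkit.core import FrameStack, ROITrace
from pawkit.synthetic import CohortSpec


@pytest.fixture
def spec() -> CohortSpec:
    return CohortSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trace(
    baseline: float = 100.0,
    n: int = 1500,
    onset: int = 500,
    fps: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> ROITrace:
    """A flat trace at `baseline` with optional noise; edit post-onset in tests."""
    rng = np.random.default_rng(seed)
    vals = np.clip(baseline + rng.normal(0, noise_sd, n), 0, 255) if noise_sd else np.full(n, float(baseline))
    return ROITrace(intensity=vals, fps=fps, onset_frame=onset, **kwargs)


def make_stack(
    frames: np.ndarray, fps: float = 1000.0, onset: int = 0
) -> FrameStack:
    return FrameStack(frames=np.asarray(frames, dtype=np.uint8), fps=fps, onset_frame=onset)
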