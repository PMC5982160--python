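import numpy as np
import pytest

from bodyangles.skeleton import Joint, SkeletonFrame, SkeletonSequence
from bodyangles.synthetic import generate_participant


def random_frame(rng: np.random.Generator, timestamp: float = 0.0) -> SkeletonFrame:
    """A frame with all 20 joints at generic positions (no degenerate bones)."""
    return SkeletonFrame(
        timestamp,
        {j: rng.uniform(-1.0, 1.0, size=3) for j in Joint},
    )


def random_sequence(
    rng: np.random.Generator, n_frames: int = 5, fps: float = 10.0
) -> SkeletonSequence:
    return SkeletonSequence(
        [random_frame(rng, timestamp=i / fps) for i in range(n_frames)], fps
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def body():
    return generate_participant(seed=42)
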