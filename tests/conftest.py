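import numpy as np
import pytest

from painstream.synthetic import SyntheticConfig, generate_dataset
from painstream.video_io import FrameSequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny synthetic dataset shared by the cheaper integration tests."""
    cfg = SyntheticConfig(n_subjects=3, trials_per_class=2, frame_size=48,
                          fps=4.0, clip_s=2.0, seed=7)
    return generate_dataset(cfg)


@pytest.fixture()
def random_gray_sequence(rng):
    frames = rng.integers(0, 256, size=(10, 8, 8), dtype=np.uint8)
    return FrameSequence(frames=frames, fps=10.0, subject_id="s0",
                         trial_id="t0", label=0)
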