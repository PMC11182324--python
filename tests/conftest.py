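import numpy as np
import pytest

from iorg.extraction import ConeSignalTable, FrameStack
from iorg.synthetic import MosaicSpec, ResponseSpec


@pytest.fixture
def small_mosaic():
    """~60-cone jittered mosaic on a 1 px/µm grid."""
    return MosaicSpec(spacing=5.0, jitter_sd=0.3, field_size=0.12, seed=1)


@pytest.fixture
def clean_response():
    """Noise-free, dropout-free, all cones responding."""
    return ResponseSpec(
        noise_sd=0.0, dropout_fraction=0.0, nonresponder_fraction=0.0, seed=2
    )


@pytest.fixture
def random_table():
    """Random 20-cone x 100-frame mean-subtracted signal table with holes."""
    rng = np.random.default_rng(42)
    sig = rng.normal(size=(20, 100))
    miss = rng.random((20, 100)) < 0.1
    return ConeSignalTable(
        signal=sig, missing=miss, cone_ids=np.arange(20),
        stimulus_frame=59, frame_rate=29.4,
    )


def make_stack(frames, frame_rate=29.4, stimulus_frame=None, valid=None, **kw):
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    if stimulus_frame is None:
        stimulus_frame = T // 2
    if valid is None:
        valid = np.ones(T, dtype=bool)
    return FrameStack(
        frames=frames, valid=valid, frame_rate=frame_rate,
        stimulus_frame=stimulus_frame, **kw,
    )
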