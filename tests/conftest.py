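import numpy as np
import pytest

from vesicletrack.detection import DetectionParams, DetectionSet
from vesicletrack.synth import make_script, render_movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return DetectionParams()


def detection_set(frame_index, points):
    """Build a DetectionSet from raw (row, col) centroids."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    return DetectionSet(frame_index, points, np.full(len(points), 9, dtype=int))


@pytest.fixture
def make_detections():
    return detection_set


@pytest.fixture(scope="session")
def merge_branch_movie():
    """Scripted movie: tracks 1+2 merge at frame 3, track 1 branches at frame 4."""
    script = make_script(
        2, 8, "oscillate",
        oscillate_radius=1.0, shape=(160, 160), min_spacing=40,
        merges=[(1, 2, 3)], branches=[(1, 4)], seed=7,
    )
    frames, truth = render_movie(script)
    return script, frames, truth


@pytest.fixture(scope="session")
def drift_movie():
    """10 well-separated tracks drifting for 20 frames, noiseless."""
    script = make_script(
        10, 20, "drift",
        drift_speed=2.0, shape=(256, 256), min_spacing=44, seed=11,
    )
    frames, truth = render_movie(script)
    return script, frames, truth
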