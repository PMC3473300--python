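import numpy as np
import pytest

from fuzzyspike import SimConfig, generate_recording
from fuzzyspike.detect import DetectionConfig
from fuzzyspike.online import SortConfig, sort_recording


@pytest.fixture(scope="session")
def easy_recording():
    """A 30 s easy-template recording at noise 0.1 with ground truth."""
    cfg = SimConfig(duration=30.0, noise_level=0.1, seed=11)
    rec, truth = generate_recording(cfg)
    return rec, truth


@pytest.fixture(scope="session")
def sorted_easy(easy_recording):
    """The full unsupervised pipeline run on the easy recording (c known)."""
    rec, _ = easy_recording
    cfg = SortConfig(
        detection=DetectionConfig(filter_signal=False), n_clusters=3, seed=0
    )
    return sort_recording(rec, cfg)


@pytest.fixture(scope="session")
def blob_scores():
    """Three tight, well-separated Gaussian blobs in 2-D with labels."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    pts = np.concatenate([c + 0.1 * rng.standard_normal((120, 2)) for c in centers])
    labels = np.repeat([0, 1, 2], 120)
    return pts, labels
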