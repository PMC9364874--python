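import numpy as np
import pytest
from hypothesis import settings

from segquant.volumes_io import LabelVolume

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def fixture_a():
    """5x5x1 grid at 1 mm: GT is a 2x2 square (4 voxels), the prediction has
    3 voxels of which 2 overlap the GT.  Counts: tp=2, fp=1, fn=2, tn=20."""
    gt = np.zeros((5, 5, 1), dtype=np.uint8)
    gt[1:3, 1:3, 0] = 1
    pred = np.zeros((5, 5, 1), dtype=np.uint8)
    pred[1, 1, 0] = 1
    pred[1, 2, 0] = 1
    pred[3, 3, 0] = 1
    return (
        LabelVolume(gt, (1.0, 1.0, 1.0), "fixture_a"),
        LabelVolume(pred, (1.0, 1.0, 1.0), "fixture_a"),
    )


def random_mask(rng, shape=(8, 8, 8), p=0.3, spacing=(1.0, 1.0, 1.0), nonempty=True):
    """Random i.i.d. binary mask; re-drawn until nonempty when requested."""
    while True:
        grid = (rng.random(shape) < p).astype(np.uint8)
        if not nonempty or grid.any():
            return LabelVolume(grid, spacing)
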