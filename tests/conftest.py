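import numpy as np
import pytest

from vasculomorph.imaging_io import BinaryMask
from vasculomorph.synthetic import TreeSpec, generate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tree_depth2():
    """Noiseless depth-2 tree (image, ground truth)."""
    return generate_tree(TreeSpec(depth=2, seed=7))


@pytest.fixture(scope="session")
def tree_depth2_mask(tree_depth2):
    _, gt = tree_depth2
    return BinaryMask(gt.stroke_mask)


def random_blob_mask(seed: int, shape=(64, 64), frac=0.3) -> np.ndarray:
    """Smooth random blob mask used for thinning/partition property tests."""
    from scipy.ndimage import gaussian_filter

    r = np.random.default_rng(seed)
    f = gaussian_filter(r.random(shape), 4)
    return f > np.quantile(f, 1 - frac)
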