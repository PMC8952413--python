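import numpy as np
import pytest

from rehabkit import quat
from rehabkit.skeleton import PoseSequence, UpperBodySkeleton


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def random_quats(rng):
    """A batch of random unit quaternions (uniform on the 3-sphere)."""

    def make(shape=()):
        if isinstance(shape, int):
            shape = (shape,)
        return quat.qnormalize(rng.normal(size=shape + (4,)))

    return make


@pytest.fixture
def skeleton():
    return UpperBodySkeleton()


@pytest.fixture
def random_pose(rng, skeleton):
    """A short random global-frame pose sequence with accelerations."""
    T, S = 24, skeleton.n_segments
    q = quat.qnormalize(rng.normal(size=(T, S, 4)))
    a = rng.normal(size=(T, S, 3))
    return PoseSequence(rate=240.0, orientations=q, accelerations=a, frame="global")
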