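import numpy as np
import pytest

from kinescore.keypoint_io import (N_LANDMARKS, Landmark, PoseFrame,
                                   PoseSequence, sequence_from_arrays)
from kinescore.synthetic import (DrivenJoint, SkeletonTemplate,
                                 SyntheticMotionSpec, simulate)


@pytest.fixture(scope="session")
def skeleton():
    return SkeletonTemplate.load()


@pytest.fixture
def make_sequence():
    """Factory for hand-built pose sequences from coordinate arrays."""

    def _make(coords, visibility=None, width=1280, height=720, fps=30.0):
        coords = np.asarray(coords, dtype=float)
        if visibility is None:
            visibility = np.ones(coords.shape[:2])
        return sequence_from_arrays(coords, visibility, width=width,
                                    height=height, fps=fps)

    return _make


@pytest.fixture
def static_sequence(make_sequence):
    """Ten identical frames of a fixed random pose."""
    rng = np.random.default_rng(7)
    pose = rng.uniform(0.2, 0.8, size=(N_LANDMARKS, 2))
    coords = np.repeat(pose[None], 10, axis=0)
    return make_sequence(coords)


@pytest.fixture
def knee_spec():
    """A clean 5-repetition squat-like knee drive."""
    return SyntheticMotionSpec(
        driven=[DrivenJoint("right_knee", baseline=60.0, rom=110.0, n_reps=5)],
        fps=30.0, duration=10.0)


@pytest.fixture
def knee_sequence(knee_spec):
    return simulate(knee_spec)
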