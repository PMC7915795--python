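import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from handkin import (
    compute_joint_angle_series,
    default_skeleton,
    fist_scenario,
    forward_kinematics,
    joints_of,
)


@pytest.fixture(scope="session")
def skeleton():
    return default_skeleton("right", 1.0)


@pytest.fixture(scope="session")
def fist_trajectories(skeleton):
    return fist_scenario(skeleton, n_frames=50, peak_flexion_deg=100.0)


@pytest.fixture(scope="session")
def fist_recording(skeleton, fist_trajectories):
    return forward_kinematics(skeleton, fist_trajectories, frame_rate=60.0)


@pytest.fixture(scope="session")
def fist_series(fist_recording):
    return compute_joint_angle_series(fist_recording)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotations(n, seed):
    """Seeded random rotation matrices (scipy, independent of the package)."""
    return Rotation.random(n, rng=np.random.default_rng(seed)).as_matrix()


@pytest.fixture(scope="session")
def joint_names(skeleton):
    return [j.name for j in joints_of(skeleton)]
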