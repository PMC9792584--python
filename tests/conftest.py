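import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sesc import (
    KinematicTree,
    PostureFrame,
    SegmentParameters,
    default_humanoid_tree,
    hinge_rotation,
)


def random_rotation(rng) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def random_posture(tree: KinematicTree, rng, root_position=None) -> PostureFrame:
    """Random admissible posture: full SO(3) at spherical joints, random
    hinge angles at hinge joints, random root pose."""
    rot = {}
    for b in tree.joint_type:
        if b == tree.root:
            continue
        if tree.joint_type[b] == "hinge":
            rot[b] = hinge_rotation(tree.hinge_axis[b], rng.uniform(-np.pi, np.pi))
        else:
            rot[b] = random_rotation(rng)
    if root_position is None:
        root_position = rng.normal(0, 0.5, size=3)
    return PostureFrame(random_rotation(rng), root_position, rot)


def random_parameters(tree: KinematicTree, rng) -> SegmentParameters:
    mass = {b: rng.uniform(1.0, 15.0) for b in tree.joint_type}
    local_com = {b: rng.normal(0, 0.2, size=3) for b in tree.joint_type}
    displacement = {b: rng.normal(0, 0.3, size=3) for b in tree.joint_type}
    return SegmentParameters(mass, local_com, displacement)


@pytest.fixture
def tree() -> KinematicTree:
    return default_humanoid_tree()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230421)


@pytest.fixture
def two_link_tree() -> KinematicTree:
    return KinematicTree({2: 1}, {1: "root", 2: "spherical"}, {}, (1, 2))
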