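"""Weighted-sum oracle vs serial-chain forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sesc import (
    KinematicTree,
    PostureFrame,
    SegmentParameters,
    SESCVector,
    brute_force_com,
    build_regressor_row,
    default_humanoid_tree,
    estimate_com,
    sesc_vector_from_parameters,
)

from conftest import random_parameters, random_posture, random_rotation

# Eq-style expansion paths of the default humanoid: each body's summand is the
# chained product of [R, d] blocks along its root-to-body path.
CHAIN_PATHS = {
    1: [1], 2: [1, 2], 3: [1, 2, 3], 4: [1, 2, 3, 4],
    5: [1, 5], 6: [1, 5, 6], 7: [1, 5, 6, 7], 8: [1, 8], 9: [1, 9],
}


def expansion_oracle(tree, params, posture):
    """Term-by-term weighted sum via explicit homogeneous-matrix products."""
    M = params.total_mass
    com = np.zeros(4)
    for b, path in CHAIN_PATHS.items():
        H = np.eye(4)
        for a in path:
            Ha = np.eye(4)
            Ha[:3, :3] = posture.rotation_of(a, tree)
            Ha[:3, 3] = (
                posture.root_position if a == tree.root else params.displacement[a]
            )
            H = H @ Ha
        com += params.mass[b] / M * (H @ np.append(params.local_com[b], 1.0))
    return com[:3]


class TestBruteForceCom:
    def test_single_body_identity_pose(self, rng):
        tree = KinematicTree({}, {1: "root"}, {}, (1,))
        C = rng.normal(size=3)
        d = rng.normal(size=3)
        params = SegmentParameters({1: 3.0}, {1: C}, {1: np.zeros(3)})
        posture = PostureFrame(np.eye(3), d, {})
        assert np.allclose(brute_force_com(tree, params, posture), d + C)

    def test_two_equal_masses_average(self, two_link_tree, rng):
        params = SegmentParameters(
            {1: 2.0, 2: 2.0},
            {1: [0.1, 0.0, 0.0], 2: [0.0, 0.2, 0.0]},
            {1: np.zeros(3), 2: [0.0, 0.0, -0.5]},
        )
        posture = PostureFrame(np.eye(3), np.zeros(3), {2: np.eye(3)})
        p = np.array([0.1, 0.0, 0.0])
        q = np.array([0.0, 0.2, -0.5])
        assert np.allclose(brute_force_com(two_link_tree, params, posture), (p + q) / 2)

    def test_matches_expansion_oracle(self, tree, rng):
        for _ in range(10):
            params = random_parameters(tree, rng)
            posture = random_posture(tree, rng)
            assert np.allclose(
                brute_force_com(tree, params, posture),
                expansion_oracle(tree, params, posture),
                atol=1e-12,
            )

    def test_missing_body_rejected(self, tree, rng):
        params = random_parameters(tree, rng)
        bad = SegmentParameters(
            {b: m for b, m in params.mass.items() if b != 9},
            params.local_com,
            params.displacement,
        )
        with pytest.raises(ValueError, match="body 9"):
            brute_force_com(tree, bad, random_posture(tree, rng))

    def test_inside_convex_hull_of_segment_coms(self, tree, rng):
        from sesc import forward_body_transforms

        params = random_parameters(tree, rng)
        posture = random_posture(tree, rng)
        fwd = forward_body_transforms(tree, posture, params.displacement)
        points = np.array([fwd[b].apply(params.local_com[b]) for b in tree.body_order])
        com = brute_force_com(tree, params, posture)
        # the weighted mean must stay within the axis-aligned bounding box
        assert np.all(com >= points.min(axis=0) - 1e-12)
        assert np.all(com <= points.max(axis=0) + 1e-12)


class TestSESCVector:
    def test_single_body_link_is_local_com(self):
        tree = KinematicTree({}, {1: "root"}, {}, (1,))
        params = SegmentParameters({1: 5.0}, {1: [0.1, 0.2, 0.3]}, {1: np.zeros(3)})
        V = sesc_vector_from_parameters(tree, params)
        assert np.allclose(V.links[1], [0.1, 0.2, 0.3])

    def test_two_link_hand_expansion(self, two_link_tree, rng):
        m1, m2 = 3.0, 7.0
        C1, C2 = rng.normal(size=3), rng.normal(size=3)
        d2 = rng.normal(size=3)
        params = SegmentParameters(
            {1: m1, 2: m2}, {1: C1, 2: C2}, {1: np.zeros(3), 2: d2}
        )
        V = sesc_vector_from_parameters(two_link_tree, params)
        M = m1 + m2
        assert np.allclose(V.links[1], (m1 * C1 + m2 * d2) / M, atol=1e-12)
        assert np.allclose(V.links[2], m2 * C2 / M, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence(self, seed):
        """The serial-chain form with the closed-form links reproduces the
        weighted sum for every random subject and posture."""
        rng = np.random.default_rng(seed)
        tree = default_humanoid_tree()
        params = random_parameters(tree, rng)
        V = sesc_vector_from_parameters(tree, params)
        for _ in range(4):
            posture = random_posture(tree, rng)
            row = build_regressor_row(tree, posture)
            est = estimate_com(row, posture.root_position, V)
            assert np.allclose(est, brute_force_com(tree, params, posture), atol=1e-12)

    def test_frame_covariance(self, tree, rng):
        """Rigidly moving the root pose moves both CoM forms identically."""
        params = random_parameters(tree, rng)
        posture = random_posture(tree, rng)
        Q = random_rotation(rng)
        t = rng.normal(size=3)
        moved = PostureFrame(
            Q @ posture.root_rotation, Q @ posture.root_position + t,
            posture.joint_rotation,
        )
        com = brute_force_com(tree, params, posture)
        com_moved = brute_force_com(tree, params, moved)
        assert np.allclose(com_moved, Q @ com + t, atol=1e-10)
        V = sesc_vector_from_parameters(tree, params)
        est_moved = estimate_com(
            build_regressor_row(tree, moved), moved.root_position, V
        )
        assert np.allclose(est_moved, Q @ com + t, atol=1e-10)

    def test_serialization_round_trip(self, tree, rng, tmp_path):
        V = sesc_vector_from_parameters(tree, random_parameters(tree, rng))
        path = tmp_path / "V.json"
        V.to_json(path)
        back = SESCVector.from_json(path)
        assert back.body_order == V.body_order
        assert np.allclose(back.stacked, V.stacked)

    def test_stacked_length_checked(self, tree):
        with pytest.raises(ValueError, match="stacked length"):
            SESCVector.from_stacked(np.zeros(10), tree.body_order)


class TestRegressorRow:
    def test_identity_posture_blocks(self, tree):
        row = build_regressor_row(tree, PostureFrame.identity(tree))
        assert np.allclose(row.full[:, :3], np.eye(3))
        for i in range(tree.n_bodies):
            assert np.allclose(row.rotation_part[:, 3 * i: 3 * i + 3], np.eye(3))
        # horizontal rows select the (AP, ML) components of each link
        V = SESCVector.from_stacked(np.arange(27.0), tree.body_order)
        horiz = row.horizontal @ V.stacked
        full = row.rotation_part @ V.stacked
        assert np.allclose(horiz, full[:2])

    def test_quarter_turn_block(self):
        from sesc import hinge_rotation

        tree = KinematicTree({}, {1: "root"}, {}, (1,))
        R = hinge_rotation(np.array([0.0, 0.0, 1.0]), np.pi / 2)
        posture = PostureFrame(R, np.zeros(3), {})
        row = build_regressor_row(tree, posture)
        assert np.allclose(row.rotation_part @ [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                           atol=1e-12)

    def test_full_row_reproduces_com(self, tree, rng):
        params = random_parameters(tree, rng)
        V = sesc_vector_from_parameters(tree, params)
        posture = random_posture(tree, rng)
        row = build_regressor_row(tree, posture)
        lhs = row.full @ np.concatenate([posture.root_position, V.stacked])
        assert np.allclose(lhs, brute_force_com(tree, params, posture), atol=1e-12)

    def test_dimension_mismatch_rejected(self, tree, two_link_tree, rng):
        row = build_regressor_row(tree, random_posture(tree, rng))
        V2 = sesc_vector_from_parameters(
            two_link_tree, random_parameters(two_link_tree, rng)
        )
        with pytest.raises(ValueError, match="body order"):
            estimate_com(row, np.zeros(3), V2)

    def test_zero_vector_gives_root_position(self, tree, rng):
        posture = random_posture(tree, rng)
        row = build_regressor_row(tree, posture)
        V0 = SESCVector.from_stacked(np.zeros(27), tree.body_order)
        assert np.allclose(
            estimate_com(row, posture.root_position, V0), posture.root_position
        )
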