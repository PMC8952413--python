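"""Skeleton model, pelvis normalization and forward kinematics."""

import numpy as np
import pytest

from rehabkit import quat
from rehabkit.skeleton import (
    PoseSequence,
    SEGMENT_NAMES,
    UpperBodySkeleton,
    denormalize,
    forward_kinematics,
    normalize_accelerations,
    normalize_orientations,
)


class TestSkeletonModel:
    def test_default_is_valid_tree(self, skeleton):
        assert skeleton.parents[0] == -1
        assert all(0 <= p < i for i, p in enumerate(skeleton.parents[1:], 1))
        assert np.all(np.linalg.norm(skeleton.offsets[1:], axis=1) > 0)

    def test_parent_order_violation_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            UpperBodySkeleton(
                names=("Pelvis", "A", "B"),
                parents=(-1, 2, 0),
                offsets=np.array([[0, 0, 0], [0, 0, 0.1], [0, 0, 0.1]]),
            )

    def test_zero_offset_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            UpperBodySkeleton(
                names=("Pelvis", "A"),
                parents=(-1, 0),
                offsets=np.array([[0, 0, 0], [0, 0, 0]]),
            )

    def test_json_round_trip(self, skeleton, tmp_path):
        p = tmp_path / "skel.json"
        skeleton.to_json(p)
        back = UpperBodySkeleton.from_json(p)
        assert back.names == skeleton.names
        assert back.parents == skeleton.parents
        assert np.allclose(back.offsets, skeleton.offsets)


class TestNormalization:
    def test_identity_pelvis_is_noop(self, rng):
        q = quat.qnormalize(rng.normal(size=(5, 15, 4)))
        q[:, 0] = [1, 0, 0, 0]
        seq = PoseSequence(rate=240, orientations=q)
        out = normalize_orientations(seq)
        assert np.allclose(np.abs(np.sum(out.orientations * q, axis=-1)), 1.0, atol=1e-12)
        assert out.frame == "pelvis-normalized"

    def test_segment_equal_to_pelvis_becomes_identity(self, random_pose):
        q = random_pose.orientations.copy()
        q[:, 3] = q[:, 0]
        seq = PoseSequence(rate=240, orientations=q, frame="global")
        out = normalize_orientations(seq)
        assert np.allclose(np.abs(out.orientations[:, 3, 0]), 1.0, atol=1e-9)
        assert np.allclose(np.abs(out.orientations[:, 0, 0]), 1.0, atol=1e-9)

    def test_reconstruction_identity(self, random_pose):
        norm = normalize_orientations(random_pose)
        pelvis = random_pose.orientations[:, 0, :]
        rebuilt = quat.qmul(pelvis[:, None, :], norm.orientations)
        dots = np.abs(np.sum(rebuilt * random_pose.orientations, axis=-1))
        assert np.allclose(dots, 1.0, atol=1e-9)

    def test_missing_pelvis_rejected(self, rng):
        seq = PoseSequence(
            rate=60,
            orientations=quat.qnormalize(rng.normal(size=(3, 2, 4))),
            segments=("LeftHand", "RightHand"),
        )
        with pytest.raises(ValueError, match="Pelvis"):
            normalize_orientations(seq)

    def test_acceleration_rotation_oracle(self):
        q = np.tile(quat.identity(), (2, 15, 1))
        q[:, 0] = quat.from_axis_angle([0, 0, 1], 90.0)
        a = np.zeros((2, 15, 3))
        a[:, 5] = [1.0, 0.0, 0.0]
        seq = PoseSequence(rate=240, orientations=q, accelerations=a)
        out = normalize_accelerations(seq)
        assert np.allclose(out.accelerations[:, 5], [0.0, -1.0, 0.0], atol=1e-12)
        # zero vectors stay zero
        assert np.allclose(out.accelerations[:, 1], 0.0)

    def test_requires_accelerations(self, rng):
        seq = PoseSequence(rate=240, orientations=quat.qnormalize(rng.normal(size=(2, 15, 4))))
        with pytest.raises(ValueError, match="acceleration"):
            normalize_accelerations(seq)


class TestDenormalize:
    def test_round_trip_is_identity(self, random_pose):
        norm = normalize_orientations(normalize_accelerations(random_pose))
        back = denormalize(norm, random_pose.orientations[:, 0, :])
        dots = np.abs(np.sum(back.orientations * random_pose.orientations, axis=-1))
        assert np.allclose(dots, 1.0, atol=1e-9)
        assert np.allclose(back.accelerations, random_pose.accelerations, atol=1e-9)

    def test_identity_track_is_noop(self, random_pose):
        norm = normalize_orientations(random_pose)
        track = np.tile(quat.identity(), (random_pose.n_frames, 1))
        out = denormalize(norm, track)
        assert np.allclose(out.orientations, norm.orientations)

    def test_single_frame_matrix_oracle(self, random_quats):
        qn = random_quats(15)[None]
        pelvis = random_quats()[None]
        seq = PoseSequence(rate=40, orientations=qn, frame="pelvis-normalized")
        out = denormalize(seq, pelvis)
        want = quat.to_matrix(pelvis[0]) @ quat.to_matrix(qn[0])
        assert np.allclose(quat.to_matrix(out.orientations[0]), want, atol=1e-12)

    def test_length_mismatch_rejected(self, random_pose):
        norm = normalize_orientations(random_pose)
        with pytest.raises(ValueError, match="match"):
            denormalize(norm, random_pose.orientations[:-1, 0, :])


class TestForwardKinematics:
    def test_identity_chain_stacks_offsets(self):
        skel = UpperBodySkeleton(
            names=("Pelvis", "A", "B", "C"),
            parents=(-1, 0, 1, 2),
            offsets=np.array([[0, 0, 0], [0, 0, 0.1], [0, 0, 0.1], [0, 0, 0.1]]),
        )
        seq = PoseSequence(rate=40, orientations=np.tile(quat.identity(), (1, 4, 1)),
                           segments=skel.names)
        pos = forward_kinematics(seq, skel)
        assert np.allclose(pos[0, :, 2], [0.0, 0.1, 0.2, 0.3], atol=1e-12)

    def test_half_turn_flips_offset(self):
        skel = UpperBodySkeleton(
            names=("Pelvis", "A"), parents=(-1, 0),
            offsets=np.array([[0, 0, 0], [0, 0, 0.5]]),
        )
        q = np.tile(quat.identity(), (1, 2, 1))
        q[0, 1] = quat.from_axis_angle([1, 0, 0], 180.0)
        seq = PoseSequence(rate=40, orientations=q, segments=skel.names)
        pos = forward_kinematics(seq, skel)
        assert np.allclose(pos[0, 1], [0, 0, -0.5], atol=1e-12)

    def test_matches_bruteforce_traversal(self, random_pose, skeleton):
        pos = forward_kinematics(random_pose, skeleton)
        # independent accumulate-down-the-tree oracle via matrices
        q = random_pose.orientations
        for f in range(random_pose.n_frames):
            ref = np.zeros((skeleton.n_segments, 3))
            for i in range(1, skeleton.n_segments):
                parent = skeleton.parents[i]
                ref[i] = ref[parent] + quat.to_matrix(q[f, i]) @ skeleton.offsets[i]
            assert np.allclose(pos[f], ref, atol=1e-9)

    def test_translation_equivariance(self, random_pose, skeleton):
        base = forward_kinematics(random_pose, skeleton)
        shifted = forward_kinematics(random_pose, skeleton, root_position=(1.0, -2.0, 0.5))
        assert np.allclose(shifted - base, [1.0, -2.0, 0.5], atol=1e-12)

    def test_rigid_body_segment_lengths(self, random_pose, skeleton):
        pos = forward_kinematics(random_pose, skeleton)
        for i in range(1, skeleton.n_segments):
            d = np.linalg.norm(pos[:, i] - pos[:, skeleton.parents[i]], axis=1)
            assert np.allclose(d, np.linalg.norm(skeleton.offsets[i]), atol=1e-9)

    def test_missing_segment_rejected(self, rng, skeleton):
        seq = PoseSequence(
            rate=40, orientations=quat.qnormalize(rng.normal(size=(2, 3, 4))),
            segments=("Pelvis", "L5", "L3"),
        )
        with pytest.raises(ValueError, match="missing"):
            forward_kinematics(seq, skeleton)
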