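"""Sensor-to-segment calibration: exact recovery, sync, fixed mapping."""

import numpy as np
import pytest

from rehabkit import quat
from rehabkit.calibration import (
    CalibrationMap,
    apply_mapping,
    choose_calibration_frame,
    compute_fixed_mapping,
    compute_variable_mapping,
    load_calibration,
    save_calibration,
    synchronize_streams,
)
from rehabkit.skeleton import PoseSequence
from rehabkit.synthetic_motion import DotEmulationConfig, MotionGenConfig, emulate_dot_stream, generate_pose_sequence


def _one_segment_seq(q, acc=None, rate=60.0, name="RightForearm"):
    return PoseSequence(
        rate=rate, orientations=np.asarray(q)[:, None, :],
        accelerations=None if acc is None else np.asarray(acc)[:, None, :],
        segments=(name,),
    )


@pytest.fixture(scope="module")
def truth():
    return generate_pose_sequence(cfg=MotionGenConfig(duration_s=3.0, seed=11))


class TestVariableMapping:
    def test_identity_when_streams_agree(self, random_quats):
        q = random_quats(20)
        m = compute_variable_mapping(q, q, q, n=4)
        assert quat.angle_between(m.q_ori, quat.identity()) < 1e-6

    def test_fixed_offset_recovered_and_recovery_exact(self, random_quats):
        q_truth = random_quats(50)
        offset = quat.from_axis_angle([1, 2, 3], 53.0)
        q_dot = quat.qmul(offset, q_truth)
        m = compute_variable_mapping(q_truth, q_truth, q_dot, n=17, segment="RightForearm")
        assert quat.angle_between(m.q_ori, quat.qinv(offset)) < 1e-6
        out = apply_mapping(m, _one_segment_seq(q_dot))
        err = quat.angle_between(out.orientations[:, 0], q_truth)
        assert np.all(err < 1e-6)

    def test_acceleration_map_uses_sensor_orientation(self, random_quats):
        q_seg, q_sens, q_dot = random_quats(10), random_quats(10), random_quats(10)
        m = compute_variable_mapping(q_seg, q_sens, q_dot, n=3)
        want = quat.qmul(q_sens[3], quat.qinv(q_dot[3]))
        assert quat.angle_between(m.q_acc, want) < 1e-6

    def test_n_invariance_for_truly_fixed_offset(self, random_quats):
        q_truth = random_quats(30)
        offset = quat.from_axis_angle([0, 1, 1], 20.0)
        q_dot = quat.qmul(offset, q_truth)
        maps = [compute_variable_mapping(q_truth, q_truth, q_dot, n=n) for n in range(10)]
        for m in maps[1:]:
            assert quat.angle_between(m.q_ori, maps[0].q_ori) < 1e-6

    def test_invalid_frame_rejected(self, random_quats):
        q = random_quats(5)
        with pytest.raises(ValueError, match="frame"):
            compute_variable_mapping(q, q, q, n=5)

    def test_segment_mismatch_rejected(self, random_quats):
        q = random_quats(5)
        m = compute_variable_mapping(q, q, q, n=0, segment="Pelvis")
        with pytest.raises(ValueError, match="segment"):
            apply_mapping(m, _one_segment_seq(q, name="LeftForearm"))

    def test_drifting_offset_error_grows_away_from_n(self, random_quats):
        q_truth = np.tile(quat.identity(), (200, 1))
        drift = quat.from_axis_angle(
            np.tile([0, 0, 1.0], (200, 1)), np.linspace(0, 20, 200)
        )
        q_dot = quat.qmul(drift, q_truth)
        n = 0
        m = compute_variable_mapping(q_truth, q_truth, q_dot, n=n, segment="RightForearm")
        err = quat.angle_between(
            apply_mapping(m, _one_segment_seq(q_dot)).orientations[:, 0], q_truth
        )
        # monotone growth away from the calibration frame
        assert err[0] < 1e-9
        assert np.all(np.diff(err) > -1e-9)


class TestSynchronization:
    def test_identical_streams_at_two_rates_align_at_zero(self, truth):
        dot = emulate_dot_stream(truth)
        a, b, spec = synchronize_streams(truth, dot)
        assert spec.offset_frames == 0
        assert a.n_frames == b.n_frames
        assert a.rate == b.rate == 40.0

    def test_injected_spike_shift_recovered(self):
        # a deliberate bump visible in both streams, half a second apart
        def stream(rate, spike_t, duration=3.0):
            T = int(duration * rate)
            q = np.tile(quat.identity(), (T, 1, 1))
            a = np.zeros((T, 1, 3))
            a[int(spike_t * rate), 0] = [0, 0, 50.0]
            return PoseSequence(rate=rate, orientations=q, accelerations=a,
                                segments=("Pelvis",))

        mvn = stream(240.0, spike_t=1.0)
        dot = stream(60.0, spike_t=1.5)  # bump 0.5 s (20 frames at 40 Hz) later
        _, _, spec = synchronize_streams(mvn, dot)
        assert abs(spec.offset_frames - (-20)) <= 1

    def test_constant_streams_fall_back_with_warning(self):
        q = np.tile(quat.identity(), (100, 1, 1))
        a = np.zeros((100, 1, 3))
        s1 = PoseSequence(rate=240, orientations=q, accelerations=a, segments=("Pelvis",))
        s2 = PoseSequence(rate=60, orientations=q[:25], accelerations=a[:25], segments=("Pelvis",))
        with pytest.warns(UserWarning, match="offset 0"):
            _, _, spec = synchronize_streams(s1, s2)
        assert spec.offset_frames == 0

    def test_requires_accelerations(self, truth):
        bare = PoseSequence(rate=truth.rate, orientations=truth.orientations,
                            segments=truth.segments)
        with pytest.raises(ValueError, match="acceleration"):
            synchronize_streams(bare, bare)


class TestQuasiStaticFrameChoice:
    def test_picks_low_acceleration_region(self):
        acc = np.ones((100, 3)) * 5.0
        acc[40:50] = 0.01
        n = choose_calibration_frame(acc)
        assert 38 <= n <= 51


class TestFixedMapping:
    def test_identical_maps_average_to_themselves(self, random_quats):
        q = random_quats()
        maps = [CalibrationMap("Pelvis", f"s{j}", q, q) for j in range(4)]
        fixed = compute_fixed_mapping(maps)
        assert fixed.session == "fixed"
        assert quat.angle_between(fixed.q_ori, q) < 1e-6

    def test_four_session_protocol(self, random_quats):
        # one map per recording session, averaged across j=4 sessions
        base = random_quats()
        wobbles = [quat.from_axis_angle([0, 0, 1], d) for d in (-4.0, -2.0, 2.0, 4.0)]
        maps = [
            CalibrationMap("Pelvis", f"s{j}", quat.qmul(w, base), quat.qmul(w, base))
            for j, w in enumerate(wobbles)
        ]
        fixed = compute_fixed_mapping(maps)
        # symmetric wobble about base: average returns to base
        assert quat.angle_between(fixed.q_ori, base) < 1e-6

    def test_common_axis_average(self):
        q0 = quat.identity()
        q90 = quat.from_axis_angle([1, 0, 0], 90.0)
        maps = [CalibrationMap("Pelvis", "a", q0, q0), CalibrationMap("Pelvis", "b", q90, q90)]
        fixed = compute_fixed_mapping(maps)
        assert quat.angle_between(fixed.q_ori, quat.from_axis_angle([1, 0, 0], 45.0)) < 1e-6

    def test_applied_error_bounded_by_session_spread(self, random_quats):
        base = random_quats()
        spread = 30.0
        wobbles = [quat.from_axis_angle([0, 1, 0], d) for d in (-spread / 2, spread / 2)]
        maps = [
            CalibrationMap("Pelvis", f"s{j}", quat.qmul(w, base), quat.qmul(w, base))
            for j, w in enumerate(wobbles)
        ]
        fixed = compute_fixed_mapping(maps)
        worst = max(quat.angle_between(fixed.q_ori, m.q_ori) for m in maps)
        assert worst <= spread + 1e-6

    def test_mixed_segments_rejected(self, random_quats):
        q = random_quats()
        maps = [CalibrationMap("Pelvis", "a", q, q), CalibrationMap("LeftForearm", "b", q, q)]
        with pytest.raises(ValueError, match="segments"):
            compute_fixed_mapping(maps)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_fixed_mapping([])


def test_calibration_json_round_trip(tmp_path, random_quats):
    maps = [CalibrationMap("Pelvis", "s1", random_quats(), random_quats(), 7)]
    p = tmp_path / "cal.json"
    save_calibration(maps, p)
    back = load_calibration(p)
    assert back[0].segment == "Pelvis"
    assert back[0].frame_index == 7
    assert quat.angle_between(back[0].q_ori, maps[0].q_ori) < 1e-12
    assert quat.angle_between(back[0].q_acc, maps[0].q_acc) < 1e-12
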