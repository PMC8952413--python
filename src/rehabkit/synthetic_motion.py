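"""Synthetic motion streams: ground-truth pose sequences and degraded
standalone-IMU emulations.

The generator produces a band-limited random walk on rotations for each
segment — not physically realistic human motion, but motion with the
right container shape, frame rates and smoothness to exercise windowing,
calibration, training and evaluation end to end. Accelerations are the
second time-derivative of forward-kinematics endpoint positions
(optionally plus gravity), expressed in the global frame.

The standalone-IMU emulation mimics a wrist/pelvis-worn sensor whose
reference frame differs from the capture system's by a fixed mounting
rotation, drifts slowly over time, and adds orientation/acceleration
noise, at a reduced 60 Hz output rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from . import quat
from .skeleton import PoseSequence, UpperBodySkeleton, forward_kinematics

__all__ = [
    "MotionGenConfig",
    "DotEmulationConfig",
    "generate_pose_sequence",
    "emulate_dot_stream",
    "make_training_corpus",
]

GRAVITY = np.array([0.0, 0.0, -9.81])  # m/s^2, Z-up global frame


@dataclass(frozen=True)
class MotionGenConfig:
    """Ground-truth stream parameters (capture-system-like, 240 Hz)."""

    duration_s: float = 10.0
    rate_hz: float = 240.0
    max_angular_speed_deg_s: float = 90.0
    smoothness_cutoff_hz: float = 1.5
    include_gravity: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        if self.max_angular_speed_deg_s < 0:
            raise ValueError("angular speed bound must be non-negative")
        if not 0 < self.smoothness_cutoff_hz < self.rate_hz / 2:
            raise ValueError("cutoff must be below the Nyquist rate")


@dataclass(frozen=True)
class DotEmulationConfig:
    """Standalone-IMU degradation parameters (60 Hz output)."""

    mounting: np.ndarray = field(default_factory=lambda: quat.identity())
    drift_deg_per_min: float = 0.0
    drift_axis: tuple = (0.0, 0.0, 1.0)
    orientation_noise_deg: float = 0.0
    acceleration_noise: float = 0.0  # m/s^2 sd
    rate_hz: float = 60.0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "mounting", quat.qnormalize(np.asarray(self.mounting, dtype=float)))
        if self.drift_deg_per_min < 0 or self.orientation_noise_deg < 0 or self.acceleration_noise < 0:
            raise ValueError("drift and noise levels must be non-negative")


def generate_pose_sequence(
    skel: UpperBodySkeleton | None = None, cfg: MotionGenConfig = MotionGenConfig()
) -> PoseSequence:
    """Smoothed random walk on rotations with FK-derived accelerations.

    Per segment, a white angular-velocity signal is low-passed at the
    smoothness cutoff and rescaled so the per-frame angular speed never
    exceeds the configured bound, then integrated into an orientation
    track. Deterministic given ``cfg.seed``.
    """
    skel = skel or UpperBodySkeleton()
    rng = np.random.default_rng(cfg.seed)
    T = max(int(round(cfg.duration_s * cfg.rate_hz)), 2)
    S = skel.n_segments
    dt = 1.0 / cfg.rate_hz

    omega = rng.normal(size=(T, S, 3))
    b, a = butter(2, cfg.smoothness_cutoff_hz / (cfg.rate_hz / 2))
    omega = filtfilt(b, a, omega, axis=0)
    speed = np.linalg.norm(omega, axis=-1)  # arbitrary units
    peak = speed.max(axis=0, keepdims=True)  # per segment
    scale = np.where(peak > 0, cfg.max_angular_speed_deg_s / np.maximum(peak, 1e-12), 0.0)
    omega = omega * scale[..., None]  # deg/s, |omega| <= bound everywhere

    q = np.empty((T, S, 4))
    # start from a small random posture offset around neutral
    q[0] = quat.from_axis_angle(rng.normal(size=(S, 3)), rng.normal(0.0, 5.0, size=S))
    for t in range(1, T):
        w = omega[t - 1]
        ang = np.linalg.norm(w, axis=-1) * dt  # degrees this step
        axis = np.where(ang[:, None] > 0, w, [1.0, 0.0, 0.0])
        dq = quat.from_axis_angle(axis, ang)
        q[t] = quat.qmul(dq, q[t - 1])

    pos = forward_kinematics(
        PoseSequence(rate=cfg.rate_hz, orientations=q, segments=skel.names), skel
    )
    acc = np.empty_like(pos)
    acc[1:-1] = (pos[2:] - 2 * pos[1:-1] + pos[:-2]) * cfg.rate_hz**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    if cfg.include_gravity:
        acc = acc + GRAVITY
    return PoseSequence(
        rate=cfg.rate_hz, orientations=q, accelerations=acc, frame="global",
        segments=skel.names,
    )


def emulate_dot_stream(truth: PoseSequence, cfg: DotEmulationConfig = DotEmulationConfig()) -> PoseSequence:
    """Degrade a ground-truth stream into a standalone-IMU-like stream.

    The emulated device reports orientations in its own reference frame,
    offset from the capture system's by ``drift(t) ∘ mounting``;
    accelerations are re-expressed in that same frame. Output decimated
    to ``cfg.rate_hz`` (the truth rate must be an integer multiple).
    """
    step = truth.rate / cfg.rate_hz
    if abs(step - round(step)) > 1e-9 or step < 1:
        raise ValueError("truth rate must be an integer multiple of the output rate")
    step = int(round(step))
    rng = np.random.default_rng(cfg.seed)

    q = truth.orientations[::step]
    acc = None if truth.accelerations is None else truth.accelerations[::step]
    T, S = q.shape[:2]
    t_min = np.arange(T) / cfg.rate_hz / 60.0

    drift = quat.from_axis_angle(
        np.broadcast_to(np.asarray(cfg.drift_axis, dtype=float), (T, 3)),
        cfg.drift_deg_per_min * t_min,
    )
    mounting = np.broadcast_to(cfg.mounting, (S, 4)) if cfg.mounting.ndim == 1 else cfg.mounting
    offset = quat.qmul(drift[:, None, :], mounting[None, :, :])  # (T, S, 4)

    q_out = quat.qmul(offset, q)
    if cfg.orientation_noise_deg > 0:
        axes = rng.normal(size=(T, S, 3))
        angles = rng.normal(0.0, cfg.orientation_noise_deg, size=(T, S))
        q_out = quat.qmul(quat.from_axis_angle(axes, angles), q_out)
    if acc is not None:
        acc = quat.rotate_vector(offset, acc)
        if cfg.acceleration_noise > 0:
            acc = acc + rng.normal(0.0, cfg.acceleration_noise, size=acc.shape)
    return PoseSequence(
        rate=cfg.rate_hz, orientations=q_out, accelerations=acc, frame="global",
        segments=truth.segments,
    )


def make_training_corpus(n_sequences: int, cfg: MotionGenConfig = MotionGenConfig(),
                         seed: int | None = None, model_cfg=None,
                         skel: UpperBodySkeleton | None = None):
    """Generate, normalize and window a reproducible training corpus.

    Returns ``(X, Y, sequences)``: stacked input windows (N, 5, 21),
    target windows (N, 5, 60), and the generated global-frame sequences.
    """
    from dataclasses import replace as _replace

    from .motion_models import ModelConfig, build_windows
    from .skeleton import normalize_accelerations, normalize_orientations

    model_cfg = model_cfg or ModelConfig()
    skel = skel or UpperBodySkeleton()
    root = np.random.default_rng(seed)
    xs, ys, seqs = [], [], []
    for _ in range(max(n_sequences, 0)):
        sub = int(root.integers(0, 2**31 - 1))
        seq = generate_pose_sequence(skel, _replace(cfg, seed=sub))
        seqs.append(seq)
        norm = normalize_accelerations(seq)
        norm = normalize_orientations(norm)
        x, y = build_windows(norm, model_cfg)
        if len(x):
            xs.append(x)
            ys.append(y)
    if not xs:
        return (
            np.empty((0, model_cfg.n_model_frames, 21)),
            np.empty((0, model_cfg.n_model_frames, 60)),
            seqs,
        )
    return np.concatenate(xs), np.concatenate(ys), seqs
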