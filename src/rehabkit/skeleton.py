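"""Upper-body skeleton, pelvis-frame normalization, and forward kinematics.

The body model covers the 15 upper-body segments of a full-body inertial
motion-capture skeleton: a spine chain from the pelvis through the head,
plus shoulder-arm-hand chains on each side. Orientations are carried per
frame and per segment as unit quaternions (see :mod:`rehabkit.quat`).

"Pelvis normalization" re-expresses every segment orientation (and,
optionally, acceleration vector) relative to the root segment:
``R_PB = R_GP^-1 R_GB`` and ``a_P = R_GP^-1 a_G``. It removes global
heading so that learned motion models generalize across facing
directions; :func:`denormalize` is its exact inverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import quat

__all__ = [
    "SEGMENT_NAMES",
    "UpperBodySkeleton",
    "PoseSequence",
    "normalize_orientations",
    "normalize_accelerations",
    "denormalize",
    "forward_kinematics",
]

#: Canonical upper-body segment order (root first, parents before children).
SEGMENT_NAMES = (
    "Pelvis", "L5", "L3", "T12", "T8", "Neck", "Head",
    "RightShoulder", "RightUpperArm", "RightForearm", "RightHand",
    "LeftShoulder", "LeftUpperArm", "LeftForearm", "LeftHand",
)

_DEFAULT_PARENTS = (-1, 0, 1, 2, 3, 4, 5, 4, 7, 8, 9, 4, 11, 12, 13)

# Neutral segment offsets in metres, local frame, Z-up right-handed global
# frame with +x forward and +y to the subject's left. Straight spine, arms
# hanging down. Plausible adult dimensions; overridable via JSON.
_DEFAULT_OFFSETS = (
    (0.0, 0.0, 0.0),        # Pelvis (root)
    (0.0, 0.0, 0.10),       # L5
    (0.0, 0.0, 0.10),       # L3
    (0.0, 0.0, 0.10),       # T12
    (0.0, 0.0, 0.12),       # T8
    (0.0, 0.0, 0.12),       # Neck
    (0.0, 0.0, 0.16),       # Head
    (0.0, -0.17, 0.06),     # RightShoulder
    (0.0, -0.03, -0.28),    # RightUpperArm
    (0.0, 0.0, -0.25),      # RightForearm
    (0.0, 0.0, -0.18),      # RightHand
    (0.0, 0.17, 0.06),      # LeftShoulder
    (0.0, 0.03, -0.28),     # LeftUpperArm
    (0.0, 0.0, -0.25),      # LeftForearm
    (0.0, 0.0, -0.18),      # LeftHand
)


@dataclass(frozen=True)
class UpperBodySkeleton:
    """Tree of segments with per-segment local offset vectors (metres)."""

    names: tuple = SEGMENT_NAMES
    parents: tuple = _DEFAULT_PARENTS
    offsets: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_OFFSETS))

    def __post_init__(self):
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        n = len(self.names)
        if len(self.parents) != n or self.offsets.shape != (n, 3):
            raise ValueError("names, parents and offsets must agree in length")
        if self.parents[0] != -1:
            raise ValueError("segment 0 must be the root (parent -1)")
        for i, p in enumerate(self.parents[1:], start=1):
            if not (0 <= p < i):
                raise ValueError(f"parent of segment {i} must precede it, got {p}")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("offsets must be finite")
        lengths = np.linalg.norm(self.offsets[1:], axis=1)
        if np.any(lengths <= 0):
            raise ValueError("non-root segments must have nonzero offsets")

    @property
    def n_segments(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_json(self, path):
        payload = {
            "names": list(self.names),
            "parents": list(self.parents),
            "offsets_m": self.offsets.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "UpperBodySkeleton":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["names"]), tuple(d["parents"]), np.array(d["offsets_m"]))


@dataclass
class PoseSequence:
    """Time-indexed per-segment orientations (+ optional accelerations).

    Parameters
    ----------
    rate : float
        Frame rate in Hz (uniform spacing).
    orientations : ndarray, shape (T, S, 4)
        Scalar-first unit quaternions per frame and segment.
    accelerations : ndarray, shape (T, S, 3), optional
        Linear accelerations in m/s^2, in the frame named by ``frame``.
    frame : {"global", "pelvis-normalized"}
    segments : tuple of str
    """

    rate: float
    orientations: np.ndarray
    accelerations: np.ndarray | None = None
    frame: str = "global"
    segments: tuple = SEGMENT_NAMES

    def __post_init__(self):
        self.orientations = quat.qnormalize(np.asarray(self.orientations, dtype=float))
        if self.orientations.ndim != 3 or self.orientations.shape[-1] != 4:
            raise ValueError("orientations must have shape (T, S, 4)")
        if self.accelerations is not None:
            self.accelerations = np.asarray(self.accelerations, dtype=float)
            if self.accelerations.shape != self.orientations.shape[:2] + (3,):
                raise ValueError("accelerations must have shape (T, S, 3)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.frame not in ("global", "pelvis-normalized"):
            raise ValueError(f"unknown frame tag {self.frame!r}")
        if len(self.segments) != self.orientations.shape[1]:
            raise ValueError("segment names must match orientation axis 1")

    @property
    def n_frames(self) -> int:
        return self.orientations.shape[0]

    @property
    def n_segments(self) -> int:
        return self.orientations.shape[1]

    def segment_index(self, name: str) -> int:
        return self.segments.index(name)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def copy(self) -> "PoseSequence":
        return replace(
            self,
            orientations=self.orientations.copy(),
            accelerations=None if self.accelerations is None else self.accelerations.copy(),
        )


def _pelvis_index(seq: PoseSequence) -> int:
    try:
        return seq.segments.index("Pelvis")
    except ValueError:
        raise ValueError("sequence has no Pelvis segment; cannot root-normalize") from None


def normalize_orientations(seq: PoseSequence) -> PoseSequence:
    """Express every segment orientation relative to the pelvis.

    Per frame, ``R_PB_i = R_GP^-1 R_GB_i``; the pelvis itself becomes the
    identity rotation. Requires a global-frame sequence.
    """
    if seq.frame != "global":
        raise ValueError("sequence must be in the global frame")
    p = _pelvis_index(seq)
    pelvis_inv = quat.qinv(seq.orientations[:, p : p + 1, :])
    out = quat.qmul(pelvis_inv, seq.orientations)
    return replace(seq, orientations=out, frame="pelvis-normalized")


def normalize_accelerations(seq: PoseSequence) -> PoseSequence:
    """Rotate global-frame acceleration vectors into the pelvis frame."""
    if seq.frame != "global":
        raise ValueError("sequence must be in the global frame")
    if seq.accelerations is None:
        raise ValueError("sequence carries no accelerations")
    p = _pelvis_index(seq)
    pelvis_inv = quat.qinv(seq.orientations[:, p : p + 1, :])
    acc = quat.rotate_vector(pelvis_inv, seq.accelerations)
    return replace(seq, accelerations=acc)


def denormalize(seq: PoseSequence, pelvis_track: np.ndarray) -> PoseSequence:
    """Undo pelvis normalization given the pelvis orientation series.

    ``R_GB = R_GP R_PB`` per frame; exact inverse of
    :func:`normalize_orientations`.
    """
    if seq.frame != "pelvis-normalized":
        raise ValueError("sequence must be pelvis-normalized")
    pelvis_track = quat.qnormalize(np.asarray(pelvis_track, dtype=float))
    if pelvis_track.shape != (seq.n_frames, 4):
        raise ValueError(
            f"pelvis track shape {pelvis_track.shape} does not match "
            f"({seq.n_frames}, 4)"
        )
    out = quat.qmul(pelvis_track[:, None, :], seq.orientations)
    acc = seq.accelerations
    if acc is not None:
        acc = quat.rotate_vector(pelvis_track[:, None, :], acc)
    return replace(seq, orientations=out, accelerations=acc, frame="global")


def forward_kinematics(
    seq: PoseSequence,
    skel: UpperBodySkeleton | None = None,
    root_position=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Segment endpoint positions, shape (T, S, 3), in metres.

    Walks the tree root-down: ``P_i = P_parent(i) + R_GB_i X_i``, with the
    root endpoint fixed at ``root_position``. Translation-equivariant in
    the root position, and each child endpoint stays exactly ``|X_i|``
    from its parent endpoint for any pose (rigid-body property).
    """
    skel = skel or UpperBodySkeleton()
    missing = [n for n in skel.names if n not in seq.segments]
    if missing:
        raise ValueError(f"sequence is missing skeleton segments: {missing}")
    idx = [seq.segments.index(n) for n in skel.names]
    q = seq.orientations[:, idx, :]
    T, S = q.shape[:2]
    pos = np.empty((T, S, 3))
    pos[:, 0, :] = np.asarray(root_position, dtype=float)
    for i in range(1, S):
        parent = skel.parents[i]
        pos[:, i, :] = pos[:, parent, :] + quat.rotate_vector(q[:, i, :], skel.offsets[i])
    return pos
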