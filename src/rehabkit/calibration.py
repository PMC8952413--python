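"""Sensor-to-capture-system calibration for standalone IMUs.

A standalone IMU worn on a body segment reports orientations in its own
reference frame, which differs from the motion-capture convention by an
(assumed fixed) rotation per recording session. The *variable mapping*
estimates that rotation from a single synchronized frame ``n``:

    R_ori = R_mvn_seg[n]  · R_dot_raw[n]^-1
    R_acc = R_mvn_sens[n] · R_dot_raw[n]^-1

and applies it to every frame of the session (orientations
left-multiplied; acceleration vectors rotated). The *fixed mapping*
averages the variable mappings of several sessions (quaternion
eigenvector average) into one cross-session calibration.

Streams are synchronized by resampling both to 40 Hz and aligning on the
cross-correlation of acceleration magnitude (an automated stand-in for
manual alignment on a deliberate bump in the recording).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import quat
from .skeleton import PoseSequence

__all__ = [
    "CalibrationMap",
    "SyncSpec",
    "synchronize_streams",
    "choose_calibration_frame",
    "compute_variable_mapping",
    "apply_mapping",
    "compute_fixed_mapping",
    "save_calibration",
    "load_calibration",
]


@dataclass(frozen=True)
class CalibrationMap:
    """Per-segment, per-session orientation and acceleration maps."""

    segment: str
    session: str
    q_ori: np.ndarray  # (4,) unit quaternion form of R^(Ori)
    q_acc: np.ndarray  # (4,) unit quaternion form of R^(Acc)
    frame_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "q_ori", quat.qnormalize(np.asarray(self.q_ori, dtype=float)))
        object.__setattr__(self, "q_acc", quat.qnormalize(np.asarray(self.q_acc, dtype=float)))

    @property
    def r_ori(self) -> np.ndarray:
        return quat.to_matrix(self.q_ori)

    @property
    def r_acc(self) -> np.ndarray:
        return quat.to_matrix(self.q_acc)


@dataclass(frozen=True)
class SyncSpec:
    """Resampling and alignment outcome for one stream pair."""

    rate_hz: float
    offset_frames: int  # shift applied to the second stream
    n_frames: int


def _resample_to(seq: PoseSequence, rate_hz: float) -> PoseSequence:
    """Linear-in-time resampling of orientations (renormalized) and accelerations."""
    if abs(seq.rate - rate_hz) < 1e-9:
        return seq.copy()
    t_src = seq.times()
    n_out = int(np.floor(t_src[-1] * rate_hz)) + 1
    t_out = np.arange(n_out) / rate_hz
    T, S = seq.orientations.shape[:2]

    def interp(arr):
        flat = arr.reshape(T, -1)
        out = np.empty((n_out, flat.shape[1]))
        for j in range(flat.shape[1]):
            out[:, j] = np.interp(t_out, t_src, flat[:, j])
        return out.reshape((n_out,) + arr.shape[1:])

    # enforce hemisphere continuity before componentwise interpolation
    qs = seq.orientations.copy()
    flips = np.sum(qs[1:] * qs[:-1], axis=-1) < 0
    sign = np.ones((T, S))
    sign[1:] = np.where(flips, -1.0, 1.0)
    qs = qs * np.cumprod(sign, axis=0)[..., None]
    q_out = quat.qnormalize(interp(qs))
    acc = None if seq.accelerations is None else interp(seq.accelerations)
    return replace(seq, rate=rate_hz, orientations=q_out, accelerations=acc)


def synchronize_streams(
    mvn: PoseSequence, dot: PoseSequence, rate_hz: float = 40.0, max_lag_s: float = 5.0
):
    """Resample both streams to ``rate_hz`` and align them in time.

    The alignment offset maximizes the cross-correlation of the
    mean-removed acceleration magnitude (averaged over segments). If
    neither stream carries a distinctive acceleration event (near-zero
    variance), the offset falls back to 0 with a warning.

    Returns ``(mvn_sync, dot_sync, spec)`` with equal lengths.
    """
    if mvn.accelerations is None or dot.accelerations is None:
        raise ValueError("both streams must carry acceleration channels")
    a = _resample_to(mvn, rate_hz)
    b = _resample_to(dot, rate_hz)
    sa = np.linalg.norm(a.accelerations, axis=-1).mean(axis=1)
    sb = np.linalg.norm(b.accelerations, axis=-1).mean(axis=1)
    sa = sa - sa.mean()
    sb = sb - sb.mean()
    if sa.std() < 1e-9 or sb.std() < 1e-9:
        warnings.warn(
            "no acceleration event to align on; falling back to offset 0", stacklevel=2
        )
        off = 0
    else:
        max_lag = int(max_lag_s * rate_hz)
        corr = np.correlate(sa, sb, mode="full")
        lags = np.arange(-len(sb) + 1, len(sa))
        keep = np.abs(lags) <= max_lag
        off = int(lags[keep][np.argmax(corr[keep])])
    # positive off: b starts `off` frames later in a's clock
    if off >= 0:
        a_lo, b_lo = off, 0
    else:
        a_lo, b_lo = 0, -off
    n = min(a.n_frames - a_lo, b.n_frames - b_lo)
    if n < 1:
        raise ValueError("streams do not overlap after alignment")

    def cut(seq, lo):
        acc = None if seq.accelerations is None else seq.accelerations[lo : lo + n]
        return replace(seq, orientations=seq.orientations[lo : lo + n], accelerations=acc)

    return cut(a, a_lo), cut(b, b_lo), SyncSpec(rate_hz=rate_hz, offset_frames=off, n_frames=n)


def choose_calibration_frame(acc: np.ndarray) -> int:
    """Default calibration frame: the most quasi-static one.

    Picks the frame minimizing a centered moving average (5 frames) of
    acceleration magnitude, reducing sensitivity to dynamics. The
    mapping is frame-invariant whenever the sensor offset is truly
    fixed, so this choice only matters under drift or noise.
    """
    mag = np.linalg.norm(np.atleast_2d(acc), axis=-1)
    if mag.ndim == 2:
        mag = mag.mean(axis=1)
    k = min(5, len(mag))
    kernel = np.ones(k) / k
    smooth = np.convolve(mag, kernel, mode="same")
    return int(np.argmin(smooth))


def compute_variable_mapping(
    mvn_seg: np.ndarray,
    mvn_sens: np.ndarray,
    dot_raw: np.ndarray,
    n: int | None = None,
    segment: str = "segment",
    session: str = "session",
    dot_acc: np.ndarray | None = None,
) -> CalibrationMap:
    """Per-session calibration from one synchronized frame ``n``.

    Parameters are (T, 4) quaternion tracks for one segment: the capture
    system's segment orientation, its sensor orientation, and the raw
    standalone-IMU orientation. When ``n`` is None it defaults to the
    most quasi-static frame (see :func:`choose_calibration_frame`) if
    ``dot_acc`` is given, else 0.
    """
    mvn_seg = quat.qnormalize(np.atleast_2d(mvn_seg))
    mvn_sens = quat.qnormalize(np.atleast_2d(mvn_sens))
    dot_raw = quat.qnormalize(np.atleast_2d(dot_raw))
    T = dot_raw.shape[0]
    if mvn_seg.shape[0] != T or mvn_sens.shape[0] != T:
        raise ValueError("streams must be synchronized to equal length")
    if n is None:
        n = choose_calibration_frame(dot_acc) if dot_acc is not None else 0
    if not 0 <= n < T:
        raise ValueError(f"calibration frame {n} outside the synchronized span [0, {T})")
    inv = quat.qinv(dot_raw[n])
    return CalibrationMap(
        segment=segment,
        session=session,
        q_ori=quat.qmul(mvn_seg[n], inv),
        q_acc=quat.qmul(mvn_sens[n], inv),
        frame_index=int(n),
    )


def apply_mapping(cmap: CalibrationMap, dot_seq: PoseSequence, segment: str | None = None) -> PoseSequence:
    """Map a raw standalone-IMU stream onto the capture convention.

    Orientations are left-multiplied by the orientation map; the
    acceleration vectors are rotated by the acceleration map. When the
    sequence carries multiple segments, ``segment`` selects the one the
    map belongs to and only that channel is returned.
    """
    if segment is None and len(dot_seq.segments) == 1:
        segment = dot_seq.segments[0]
    if segment != cmap.segment:
        raise ValueError(
            f"calibration map is for segment {cmap.segment!r}, stream offers {segment!r}"
        )
    idx = dot_seq.segments.index(segment)
    q = quat.qmul(cmap.q_ori, dot_seq.orientations[:, idx, :])
    acc = None
    if dot_seq.accelerations is not None:
        acc = quat.rotate_vector(cmap.q_acc, dot_seq.accelerations[:, idx, :])
    return PoseSequence(
        rate=dot_seq.rate,
        orientations=q[:, None, :],
        accelerations=None if acc is None else acc[:, None, :],
        frame=dot_seq.frame,
        segments=(segment,),
    )


def compute_fixed_mapping(maps: list) -> CalibrationMap:
    """Cross-session calibration: quaternion average of session maps."""
    if not maps:
        raise ValueError("need at least one session map")
    segments = {m.segment for m in maps}
    if len(segments) > 1:
        raise ValueError(f"cannot average maps across segments {sorted(segments)}")
    return CalibrationMap(
        segment=maps[0].segment,
        session="fixed",
        q_ori=quat.quat_average(np.stack([m.q_ori for m in maps])),
        q_acc=quat.quat_average(np.stack([m.q_acc for m in maps])),
        frame_index=maps[0].frame_index,
    )


def save_calibration(maps: list, path):
    payload = [
        {
            "segment": m.segment,
            "session": m.session,
            "q_ori": m.q_ori.tolist(),
            "q_acc": m.q_acc.tolist(),
            "frame_index": m.frame_index,
        }
        for m in maps
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_calibration(path) -> list:
    data = json.loads(Path(path).read_text())
    return [
        CalibrationMap(
            segment=d["segment"], session=d["session"], q_ori=np.array(d["q_ori"]),
            q_acc=np.array(d["q_acc"]), frame_index=d["frame_index"],
        )
        for d in data
    ]
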