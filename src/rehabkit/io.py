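"""File formats: CSV time series with JSON sidecars, stick-figure export.

Motion time series are long-format CSV (one row per frame and segment)
with columns ``time_s, stream_id, qw, qx, qy, qz[, ax, ay, az]``; RSS
traces use ``time_s, stream_id, rss_dbm``. A sidecar JSON (same path
plus ``.meta.json``) records the frame rate, reference-frame tag and
units; readers validate monotone time, sidecar-vs-data rate consistency
(within 1%), and quaternion unit norms (within 1e-6).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rss import RSSTrace
from .skeleton import PoseSequence, UpperBodySkeleton, forward_kinematics

__all__ = [
    "write_motion_csv",
    "read_motion_csv",
    "write_rss_csv",
    "read_rss_csv",
    "export_stick_figure",
]

_MOTION_COLS = ["time_s", "stream_id", "qw", "qx", "qy", "qz"]
_ACC_COLS = ["ax", "ay", "az"]


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_motion_csv(seq: PoseSequence, path):
    """Write a pose sequence and its metadata sidecar."""
    T, S = seq.orientations.shape[:2]
    t = np.repeat(seq.times(), S)
    sid = np.tile(np.asarray(seq.segments), T)
    q = seq.orientations.reshape(-1, 4)
    data = {"time_s": t, "stream_id": sid,
            "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3]}
    if seq.accelerations is not None:
        a = seq.accelerations.reshape(-1, 3)
        data.update({"ax": a[:, 0], "ay": a[:, 1], "az": a[:, 2]})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "kind": "motion",
        "rate_hz": seq.rate,
        "frame": seq.frame,
        "segments": list(seq.segments),
        "units": {"time_s": "s", "q": "unit quaternion (w,x,y,z)", "a": "m/s^2"},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_motion_csv(path) -> PoseSequence:
    df = pd.read_csv(path)
    missing = [c for c in _MOTION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    meta = json.loads(_sidecar(path).read_text())
    segments = tuple(meta["segments"])
    rate = float(meta["rate_hz"])
    S = len(segments)
    if len(df) % S:
        raise ValueError(f"{path}: row count {len(df)} not divisible by {S} segments")
    T = len(df) // S
    times = df["time_s"].to_numpy().reshape(T, S)[:, 0]
    if T > 1:
        dt = np.diff(times)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"{path}: non-monotone time at frame {bad}")
        med = np.median(dt)
        if abs(med - 1.0 / rate) > 0.01 / rate:
            raise ValueError(
                f"{path}: sidecar rate {rate} Hz inconsistent with median spacing "
                f"{med:.6g} s (>1% off)"
            )
    q = df[["qw", "qx", "qy", "qz"]].to_numpy().reshape(T, S, 4)
    norms = np.linalg.norm(q, axis=-1)
    bad = np.abs(norms - 1.0) > 1e-6
    if np.any(bad):
        frame, seg = np.argwhere(bad)[0]
        line = int(frame) * S + int(seg) + 2  # header is line 1
        raise ValueError(f"{path}: non-unit quaternion at line {line}")
    acc = None
    if all(c in df.columns for c in _ACC_COLS):
        acc = df[_ACC_COLS].to_numpy().reshape(T, S, 3)
    return PoseSequence(rate=rate, orientations=q, accelerations=acc,
                        frame=meta.get("frame", "global"), segments=segments)


def write_rss_csv(trace: RSSTrace, path, step_interval_s: float = 0.1):
    T, U = trace.values.shape
    df = pd.DataFrame({
        "time_s": np.repeat(np.arange(T) * step_interval_s, U),
        "stream_id": np.tile([f"anchor{u}" for u in range(U)], T),
        "rss_dbm": trace.values.ravel(),
    })
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"kind": "rss", "step_interval_s": step_interval_s,
            "n_anchors": U, "clipped": trace.clipped, "units": {"rss_dbm": "dBm"}}
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_rss_csv(path) -> tuple:
    df = pd.read_csv(path)
    for c in ("time_s", "stream_id", "rss_dbm"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    meta = json.loads(_sidecar(path).read_text())
    U = int(meta["n_anchors"])
    if len(df) % U:
        raise ValueError(f"{path}: row count not divisible by {U} anchors")
    values = df["rss_dbm"].to_numpy().reshape(-1, U)
    trace = RSSTrace(values=values, clipped=bool(meta.get("clipped", False)))
    return trace, float(meta["step_interval_s"])


def export_stick_figure(seq: PoseSequence, path, skel: UpperBodySkeleton | None = None,
                        root_position=(0.0, 0.0, 0.0)):
    """Write per-frame segment line endpoints (metres) for plotting.

    CSV columns: frame, segment, parent, then the parent endpoint and
    the segment endpoint coordinates — one drawable line per row.
    """
    skel = skel or UpperBodySkeleton()
    rows = []
    if seq.n_frames:
        pos = forward_kinematics(seq, skel, root_position)
        for f in range(pos.shape[0]):
            for i in range(1, skel.n_segments):
                p = skel.parents[i]
                rows.append((f, skel.names[i], skel.names[p], *pos[f, p], *pos[f, i]))
    pd.DataFrame(
        rows,
        columns=["frame", "segment", "parent", "x0", "y0", "z0", "x1", "y1", "z1"],
    ).to_csv(path, index=False, float_format="%.17g")
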