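"""Orientation and joint-angle evaluation metrics.

The headline orientation metric is the mean angular error: the average,
over frames and segments, of the relative rotation angle between
predicted and ground-truth orientations (degrees, sign-invariant under
the quaternion double cover). Joint angles collapse the relative
rotation between the two segments flanking a joint into a single angle —
for the elbow, 0° is a straight arm; for the shoulder the three degrees
of freedom are deliberately not distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quat
from .skeleton import PoseSequence

__all__ = [
    "JOINTS",
    "EvaluationReport",
    "mean_angular_error",
    "joint_angle",
    "joint_angle_error",
    "error_histograms",
    "evaluate",
]

#: Named joints as (proximal, distal) segment pairs.
JOINTS = {
    "RightElbow": ("RightUpperArm", "RightForearm"),
    "LeftElbow": ("LeftUpperArm", "LeftForearm"),
    "RightShoulder": ("T8", "RightUpperArm"),
    "LeftShoulder": ("T8", "LeftUpperArm"),
}


@dataclass(frozen=True)
class EvaluationReport:
    """Angular-error summary of a predicted sequence against ground truth."""

    overall_deg: float
    per_segment_deg: dict
    joint_error_mean_deg: dict
    joint_error_sd_deg: dict

    def to_dict(self) -> dict:
        return {
            "overall_mean_angular_error_deg": self.overall_deg,
            "per_segment_mean_angular_error_deg": self.per_segment_deg,
            "joint_angle_error_mean_deg": self.joint_error_mean_deg,
            "joint_angle_error_sd_deg": self.joint_error_sd_deg,
        }


def _orientations(x) -> tuple:
    if isinstance(x, PoseSequence):
        return x.orientations, x.segments
    arr = np.asarray(x, dtype=float)
    return arr, None


def mean_angular_error(pred, truth):
    """Overall and per-segment mean angular error in degrees.

    The overall value is the mean over all (frame, segment) pairs —
    identical to the mean of per-segment means only when every segment
    contributes the same number of frames (it does here, but the
    distinction matters when concatenating unequal sequences).
    """
    p, _ = _orientations(pred)
    t, _ = _orientations(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    ang = quat.angle_between(p, t)  # (T, S)
    return float(ang.mean()), ang.mean(axis=0)


def joint_angle(seq, joint: str) -> np.ndarray:
    """Per-frame joint angle (degrees): the smallest rotation between the
    two segment orientations flanking the joint."""
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}; choose from {sorted(JOINTS)}")
    prox, dist = JOINTS[joint]
    q, segments = _orientations(seq)
    if segments is None:
        raise ValueError("joint_angle needs a PoseSequence with named segments")
    i, j = segments.index(prox), segments.index(dist)
    return quat.angle_between(q[:, i, :], q[:, j, :])


def joint_angle_error(pred, truth, joint: str):
    """Signed per-frame joint-angle error: inferred minus ground truth.

    Negative values mean the inferred joint angle was more acute than
    the ground truth (for the elbow: predicted arm straighter).
    Returns ``(errors, mean, sd)`` in degrees.
    """
    a_pred = joint_angle(pred, joint)
    a_true = joint_angle(truth, joint)
    if a_pred.shape != a_true.shape:
        raise ValueError("sequences must have equal length")
    err = a_pred - a_true
    return err, float(err.mean()), float(err.std())


def error_histograms(values, bin_width: float):
    """Histogram with fixed-width bins; counts conserve the sample size.

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("histogram values must be finite")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts


def evaluate(pred: PoseSequence, truth: PoseSequence) -> EvaluationReport:
    """Full evaluation: segment orientation errors plus joint-angle errors."""
    overall, per_seg = mean_angular_error(pred, truth)
    seg_names = truth.segments if isinstance(truth, PoseSequence) else None
    per_segment = {n: float(v) for n, v in zip(seg_names, per_seg)}
    jmean, jsd = {}, {}
    for joint in JOINTS:
        try:
            _, m, s = joint_angle_error(pred, truth, joint)
        except ValueError:
            continue
        jmean[joint] = m
        jsd[joint] = s
    return EvaluationReport(
        overall_deg=overall, per_segment_deg=per_segment,
        joint_error_mean_deg=jmean, joint_error_sd_deg=jsd,
    )
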