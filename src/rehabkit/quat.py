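"""Unit-quaternion rotation algebra.

Quaternions are stored scalar-first as ``(..., 4)`` float arrays
``[w, x, y, z]``. All functions are vectorized over leading axes and
renormalize their results, so unit norm is preserved to well below 1e-9
through arbitrarily long chains of operations.

A quaternion ``q`` and its negation ``-q`` encode the same rotation
(double cover); every angle computation here is invariant to that sign.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "qnormalize",
    "qmul",
    "qinv",
    "angle_between",
    "quat_average",
    "to_matrix",
    "from_matrix",
    "rotate_vector",
    "from_axis_angle",
    "identity",
]

_EPS = 1e-12


def _asquat(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion array must have last axis 4, got shape {q.shape}")
    if not np.all(np.isfinite(q)):
        raise ValueError("quaternion components must be finite")
    return q


def identity(shape: tuple = ()) -> np.ndarray:
    """Identity rotation(s) of the given leading shape."""
    q = np.zeros(shape + (4,))
    q[..., 0] = 1.0
    return q


def qnormalize(q) -> np.ndarray:
    """Rescale to unit norm; rejects (near-)zero quaternions."""
    q = _asquat(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-8):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def qmul(a, b) -> np.ndarray:
    """Hamilton product a∘b (apply b first, then a), renormalized."""
    a = _asquat(a)
    b = _asquat(b)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    return qnormalize(out)


def qinv(q) -> np.ndarray:
    """Inverse rotation (conjugate for unit quaternions)."""
    q = qnormalize(q)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def angle_between(a, b) -> np.ndarray:
    """Relative rotation angle between two orientations, in degrees.

    theta = (360/pi) * arccos(clamp(|<a, b>|, 0, 1)), in [0, 180]. The
    absolute value makes the angle invariant to the quaternion double
    cover, so upstream sign conventions never matter.

    Evaluated in the equivalent atan2 form on the difference rotation
    q_d = a^-1 b (|<a,b>| = |q_d.w|, sin(theta/2) = |q_d.vec|), which
    stays fully accurate near 0 deg where arccos loses half the
    significant digits.
    """
    d = qmul(qinv(a), b)
    half = np.arctan2(np.linalg.norm(d[..., 1:], axis=-1), np.abs(d[..., 0]))
    return np.degrees(2.0 * half)


def quat_average(qs) -> np.ndarray:
    """Average a set of orientations (Markley eigenvector method).

    Returns the unit eigenvector of ``sum_i q_i q_i^T`` with the largest
    eigenvalue. Sign flips of any input leave the outer products, and
    hence the average rotation, unchanged.
    """
    qs = _asquat(qs)
    qs = np.atleast_2d(qs)
    if qs.size == 0:
        raise ValueError("quat_average requires at least one quaternion")
    qs = qnormalize(qs)
    m = np.einsum("ni,nj->ij", qs.reshape(-1, 4), qs.reshape(-1, 4))
    w, v = np.linalg.eigh(m)
    return qnormalize(v[:, -1])


def to_matrix(q) -> np.ndarray:
    """Rotation matrix (3x3, batched over leading axes) for q."""
    q = qnormalize(q)
    w, x, y, z = (q[..., i] for i in range(4))
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def from_matrix(m, atol: float = 1e-6) -> np.ndarray:
    """Quaternion for a proper rotation matrix (Shepperd's method).

    Rejects matrices that are not orthonormal with determinant +1 within
    ``atol``, reporting the measured deviation.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) matrix, got shape {m.shape}")
    ortho_dev = np.max(np.abs(np.swapaxes(m, -1, -2) @ m - np.eye(3)))
    det_dev = np.max(np.abs(np.linalg.det(m) - 1.0))
    if ortho_dev > atol or det_dev > atol:
        raise ValueError(
            "matrix is not a proper rotation: orthonormality deviation "
            f"{ortho_dev:.3e}, determinant deviation {det_dev:.3e} (atol={atol:.1e})"
        )
    batch = m.shape[:-2]
    mm = m.reshape((-1, 3, 3))
    q = np.empty((mm.shape[0], 4))
    for k, r in enumerate(mm):
        tr = np.trace(r)
        if tr > 0:
            s = np.sqrt(tr + 1.0) * 2
            q[k] = [0.25 * s, (r[2, 1] - r[1, 2]) / s, (r[0, 2] - r[2, 0]) / s, (r[1, 0] - r[0, 1]) / s]
        elif r[0, 0] >= r[1, 1] and r[0, 0] >= r[2, 2]:
            s = np.sqrt(1.0 + r[0, 0] - r[1, 1] - r[2, 2]) * 2
            q[k] = [(r[2, 1] - r[1, 2]) / s, 0.25 * s, (r[0, 1] + r[1, 0]) / s, (r[0, 2] + r[2, 0]) / s]
        elif r[1, 1] >= r[2, 2]:
            s = np.sqrt(1.0 + r[1, 1] - r[0, 0] - r[2, 2]) * 2
            q[k] = [(r[0, 2] - r[2, 0]) / s, (r[0, 1] + r[1, 0]) / s, 0.25 * s, (r[1, 2] + r[2, 1]) / s]
        else:
            s = np.sqrt(1.0 + r[2, 2] - r[0, 0] - r[1, 1]) * 2
            q[k] = [(r[1, 0] - r[0, 1]) / s, (r[0, 2] + r[2, 0]) / s, (r[1, 2] + r[2, 1]) / s, 0.25 * s]
    return qnormalize(q.reshape(batch + (4,)))


def rotate_vector(q, v) -> np.ndarray:
    """Rotate 3-vector(s) v by quaternion(s) q."""
    q = qnormalize(q)
    v = np.asarray(v, dtype=float)
    u = q[..., 1:]
    w = q[..., :1]
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def from_axis_angle(axis, angle_deg) -> np.ndarray:
    """Quaternion for a rotation of ``angle_deg`` degrees about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(n < _EPS):
        raise ValueError("rotation axis must be nonzero")
    axis = axis / n
    half = 0.5 * np.radians(np.asarray(angle_deg, dtype=float))
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )
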