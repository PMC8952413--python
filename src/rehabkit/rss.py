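"""Bluetooth received-signal-strength simulation.

Log-distance path-loss model with log-normal shadowing: the RSS (dBm)
received from anchor ``u`` at distance ``d_u`` is

    nu_u = P_t - PL_u(d0) - 10 xi_u log10(d_u / d0) + N(0, sigma_u^2)

where ``PL_u(d0)`` is the path loss at reference distance ``d0``,
``xi_u`` the path-loss exponent, and the Gaussian term models slow
fading due to obstructions. Receivers clip reported values into
[-100, -50] dBm; vicinity labels mark whether the target is within a
radius of each anchor — the ground truth for proximity reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PropagationParams",
    "AnchorScene",
    "Trajectory",
    "RSSTrace",
    "default_scene",
    "simulate_rss",
    "clip_rss",
    "bounded_random_walk",
    "vicinity_labels",
]

RSS_FLOOR = -100.0  # dBm
RSS_CEIL = -50.0  # dBm


@dataclass(frozen=True)
class PropagationParams:
    """Per-anchor log-distance channel characteristics."""

    tx_power_dbm: float = -10.0
    ref_path_loss_db: float = 40.0
    ref_distance_m: float = 1.0
    path_loss_exponent: float = 2.5
    shadowing_sd_db: float = 7.5

    def __post_init__(self):
        if self.ref_distance_m <= 0:
            raise ValueError("reference distance must be positive")
        if self.shadowing_sd_db < 0:
            raise ValueError("shadowing sd must be non-negative")


@dataclass(frozen=True)
class AnchorScene:
    """Fixed anchors with known 2D coordinates inside rectangular bounds."""

    anchors: np.ndarray  # (U, 2) metres
    params: tuple  # U PropagationParams
    bounds: tuple = ((0.0, 50.0), (0.0, 50.0))

    def __post_init__(self):
        object.__setattr__(self, "anchors", np.atleast_2d(np.asarray(self.anchors, dtype=float)))
        if self.anchors.shape[0] < 1 or self.anchors.shape[1] != 2:
            raise ValueError("anchors must be a (U, 2) array with U >= 1")
        if len(self.params) != self.anchors.shape[0]:
            raise ValueError("one PropagationParams per anchor required")
        (x0, x1), (y0, y1) = self.bounds
        if np.any(self.anchors[:, 0] < x0) or np.any(self.anchors[:, 0] > x1) or \
           np.any(self.anchors[:, 1] < y0) or np.any(self.anchors[:, 1] > y1):
            raise ValueError("anchors must lie within the scene bounds")

    @property
    def n_anchors(self) -> int:
        return self.anchors.shape[0]


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 2D target positions."""

    positions: np.ndarray  # (T, 2) metres
    step_interval_s: float = 0.1

    def __post_init__(self):
        object.__setattr__(self, "positions", np.atleast_2d(np.asarray(self.positions, dtype=float)))
        if self.positions.shape[1] != 2:
            raise ValueError("positions must be (T, 2)")
        if self.step_interval_s <= 0:
            raise ValueError("step interval must be positive")

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class RSSTrace:
    """Per-step RSS vectors from all anchors, in dBm."""

    values: np.ndarray  # (T, U) dBm
    clipped: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values", np.atleast_2d(np.asarray(self.values, dtype=float)))
        if self.clipped and (
            np.any(self.values < RSS_FLOOR) or np.any(self.values > RSS_CEIL)
        ):
            raise ValueError("clipped trace has values outside [-100, -50] dBm")


# Default exponents for the ten-anchor rehabilitation-center scene. The
# spread (2.1-3.0) covers typical indoor BLE conditions from near free
# space to cluttered rooms; with P_t - PL(d0) = -50 dBm the mean RSS
# meets the clipping ceiling exactly at the 1 m reference distance and
# falls to roughly -96 dBm across the 50 m diagonal.
_DEFAULT_EXPONENTS = (2.2, 2.4, 2.6, 2.8, 3.0, 2.3, 2.5, 2.7, 2.9, 2.1)


def default_scene(shadowing_sd_db: float = 7.5) -> AnchorScene:
    """The 50 m x 50 m, 10-anchor simulated rehabilitation center.

    The floor is divided into ten 10 m x 25 m subcenters (5 columns x 2
    rows) with one anchor at the middle of each.
    """
    xs = [5.0, 15.0, 25.0, 35.0, 45.0]
    ys = [12.5, 37.5]
    anchors = np.array([(x, y) for y in ys for x in xs])
    params = tuple(
        PropagationParams(path_loss_exponent=e, shadowing_sd_db=shadowing_sd_db)
        for e in _DEFAULT_EXPONENTS
    )
    return AnchorScene(anchors=anchors, params=params)


def simulate_rss(scene: AnchorScene, traj: Trajectory, seed=None) -> RSSTrace:
    """Simulate the RSS trace received along a trajectory (unclipped)."""
    rng = np.random.default_rng(seed)
    d = np.linalg.norm(
        traj.positions[:, None, :] - scene.anchors[None, :, :], axis=-1
    )  # (T, U)
    d0 = np.array([p.ref_distance_m for p in scene.params])
    if np.any(d < d0):
        warnings.warn(
            "target within the reference distance of an anchor; distance floored at d0",
            stacklevel=2,
        )
        d = np.maximum(d, d0)
    xi = np.array([p.path_loss_exponent for p in scene.params])
    pt = np.array([p.tx_power_dbm for p in scene.params])
    pl0 = np.array([p.ref_path_loss_db for p in scene.params])
    sd = np.array([p.shadowing_sd_db for p in scene.params])
    mean = pt - pl0 - 10.0 * xi * np.log10(d / d0)
    shadow = rng.normal(0.0, 1.0, size=d.shape) * sd
    return RSSTrace(values=mean + shadow, clipped=False)


def clip_rss(trace: RSSTrace) -> RSSTrace:
    """Clamp RSS values into the receiver's reporting range [-100, -50] dBm."""
    return RSSTrace(values=np.clip(trace.values, RSS_FLOOR, RSS_CEIL), clipped=True)


def bounded_random_walk(
    bounds, n_steps: int, step_sd_m: float = 0.5, seed=None, start=None,
    step_interval_s: float = 0.1,
) -> Trajectory:
    """Reflective Gaussian random walk inside rectangular bounds."""
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(seed)
    (x0, x1), (y0, y1) = bounds
    lo = np.array([x0, y0])
    hi = np.array([x1, y1])
    pos = np.empty((n_steps, 2))
    pos[0] = np.asarray(start, dtype=float) if start is not None else lo + (hi - lo) * rng.random(2)
    pos[0] = _reflect(pos[0], lo, hi)
    for t in range(1, n_steps):
        pos[t] = _reflect(pos[t - 1] + rng.normal(0.0, step_sd_m, size=2), lo, hi)
    return Trajectory(positions=pos, step_interval_s=step_interval_s)


def _reflect(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    # fold the line into [lo, hi] by reflecting at the walls
    q = np.mod(p - lo, 2 * span)
    q = np.where(q > span, 2 * span - q, q)
    return lo + q


def vicinity_labels(scene: AnchorScene, traj: Trajectory, radius_m: float = 15.0) -> np.ndarray:
    """Binary (T, U) labels: 1 iff the target is within ``radius_m`` of the anchor.

    The boundary (distance exactly equal to the radius) counts as in
    vicinity.
    """
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    d = np.linalg.norm(
        traj.positions[:, None, :] - scene.anchors[None, :, :], axis=-1
    )
    return (d <= radius_m).astype(int)
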