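"""RSS fingerprint codebook and k-NN centroid localization.

During training, the mean RSS vector from all anchors is recorded at
each reference point of a room grid (the *fingerprint*), paired with the
point's 3D coordinates. At test time a fresh fingerprint is matched to
the codebook by Euclidean distance; the location estimate is the
centroid of the ``W`` nearest reference coordinates (``W = 3`` by
default). Anchors that go silent during a test bin are filled with the
minimum reportable RSS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .rss import RSS_CEIL, RSS_FLOOR

__all__ = [
    "FingerprintCodebook",
    "build_codebook",
    "preprocess_test_rss",
    "closest_fingerprints",
    "position_estimate",
    "evaluate_localization",
    "FingerprintLocalizer",
]

NU_MIN = -100.0  # dBm; coincides with the clipping floor


@dataclass
class FingerprintCodebook:
    """Reference fingerprints F and coordinates D, indexed (room, i, j)."""

    keys: list  # (i, j, k) tuples, insertion-ordered
    fingerprints: np.ndarray  # (N, U) mean RSS, dBm
    coordinates: np.ndarray  # (N, 3) metres

    def __post_init__(self):
        self.fingerprints = np.atleast_2d(np.asarray(self.fingerprints, dtype=float))
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if len(self.keys) != len(set(map(tuple, self.keys))):
            raise ValueError("codebook indices must be unique")
        if self.fingerprints.shape[0] != len(self.keys):
            raise ValueError("one fingerprint per key required")
        if self.coordinates.shape != (len(self.keys), 3):
            raise ValueError("coordinates must be (N, 3)")

    @property
    def n_entries(self) -> int:
        return len(self.keys)

    @property
    def n_anchors(self) -> int:
        return self.fingerprints.shape[1]

    def to_json(self, path):
        payload = {
            "nu_min_dbm": NU_MIN,
            "entries": [
                {"index": list(k), "fingerprint_dbm": f.tolist(), "coordinate_m": c.tolist()}
                for k, f, c in zip(self.keys, self.fingerprints, self.coordinates)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "FingerprintCodebook":
        d = json.loads(Path(path).read_text())
        keys = [tuple(e["index"]) for e in d["entries"]]
        fps = np.array([e["fingerprint_dbm"] for e in d["entries"]])
        coords = np.array([e["coordinate_m"] for e in d["entries"]])
        return cls(keys, fps, coords)


def build_codebook(recordings: dict, coordinates: dict, clip: bool = True) -> FingerprintCodebook:
    """Time-average per-point RSS recordings into a codebook.

    Parameters
    ----------
    recordings : dict mapping (i, j, k) -> (T, U) RSS arrays in dBm.
        NaN marks packets never received; an anchor with no packets at
        all is stored as the floor value with a warning.
    coordinates : dict mapping the same keys -> length-3 coordinates (m).
    clip : clamp stored fingerprints into [-100, -50] dBm (consistent
        with the receiver clipping applied to test data).
    """
    if set(recordings) != set(coordinates):
        raise ValueError("recordings and coordinates must cover the same reference points")
    keys, fps, coords = [], [], []
    for key in recordings:
        trace = np.atleast_2d(np.asarray(recordings[key], dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(trace, axis=0)
        if np.any(np.isnan(mean)):
            warnings.warn(
                f"reference point {key}: anchor(s) {np.flatnonzero(np.isnan(mean)).tolist()} "
                "never heard; stored as nu_min", stacklevel=2,
            )
            mean = np.where(np.isnan(mean), NU_MIN, mean)
        if clip:
            mean = np.clip(mean, RSS_FLOOR, RSS_CEIL)
        keys.append(tuple(key))
        fps.append(mean)
        coords.append(np.asarray(coordinates[key], dtype=float))
    return FingerprintCodebook(keys, np.array(fps), np.array(coords))


def preprocess_test_rss(
    packets: list, n_anchors: int, bin_s: float = 0.25, nu_min: float = NU_MIN
) -> np.ndarray:
    """Bin time-stamped packets to 4 Hz per-anchor mean RSS.

    ``packets`` is a list of ``(time_s, anchor_id, rss_dbm)`` triples.
    Returns (n_bins, U) fingerprints; bins where an anchor is silent are
    filled with ``nu_min``.
    """
    if not len(packets):
        raise ValueError("no packets to preprocess")
    arr = np.asarray(packets, dtype=float)
    t, aid, v = arr[:, 0], arr[:, 1].astype(int), arr[:, 2]
    if np.any(aid < 0) or np.any(aid >= n_anchors):
        raise ValueError("anchor id out of range")
    bins = np.floor((t - t.min()) / bin_s).astype(int)
    n_bins = bins.max() + 1
    sums = np.zeros((n_bins, n_anchors))
    counts = np.zeros((n_bins, n_anchors))
    np.add.at(sums, (bins, aid), v)
    np.add.at(counts, (bins, aid), 1)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    return np.where(counts > 0, out, nu_min)


def closest_fingerprints(cb: FingerprintCodebook, g: np.ndarray, w: int = 3) -> np.ndarray:
    """Indices of the W codebook entries nearest to fingerprint ``g``.

    Euclidean norm over the U RSS values; ascending by distance, ties
    broken by codebook insertion order (stable sort).
    """
    g = np.asarray(g, dtype=float).ravel()
    if g.shape[0] != cb.n_anchors:
        raise ValueError("fingerprint length does not match codebook anchors")
    if not (1 <= w <= cb.n_entries):
        raise ValueError(f"W must be in [1, {cb.n_entries}]")
    dist = np.linalg.norm(cb.fingerprints - g, axis=1)
    return np.argsort(dist, kind="stable")[:w]


def position_estimate(cb: FingerprintCodebook, indices) -> np.ndarray:
    """Centroid of the selected reference coordinates (metres)."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty index set")
    return cb.coordinates[indices].mean(axis=0)


def evaluate_localization(estimates, truths):
    """Mean squared Euclidean error (m^2) and per-point distances (m)."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    truths = np.atleast_2d(np.asarray(truths, dtype=float))
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must align")
    d = np.linalg.norm(estimates - truths, axis=1)
    return float(np.mean(d**2)), d


class FingerprintLocalizer(BaseEstimator, RegressorMixin):
    """k-NN centroid localizer over a fingerprint codebook.

    ``fit`` accepts fingerprints (N, U) and reference coordinates (N, 3);
    ``predict`` maps test fingerprints to coordinate estimates as the
    centroid of the ``w`` nearest codebook entries.
    """

    def __init__(self, w: int = 3):
        self.w = w

    def fit(self, X, y, keys=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        keys = keys if keys is not None else [(0, i, 0) for i in range(X.shape[0])]
        self.codebook_ = FingerprintCodebook(list(keys), X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "codebook_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array(
            [
                position_estimate(self.codebook_, closest_fingerprints(self.codebook_, g, self.w))
                for g in X
            ]
        )
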