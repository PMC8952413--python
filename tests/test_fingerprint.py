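"""Fingerprint codebook construction and k-NN centroid localization."""

import numpy as np
import pytest

from rehabkit.fingerprint import (
    FingerprintCodebook,
    FingerprintLocalizer,
    build_codebook,
    closest_fingerprints,
    evaluate_localization,
    position_estimate,
    preprocess_test_rss,
)
from rehabkit.rss import (
    AnchorScene,
    PropagationParams,
    Trajectory,
    clip_rss,
    simulate_rss,
)


def _random_codebook(rng, n=20, u=4):
    fps = rng.uniform(-100, -50, size=(n, u))
    coords = rng.uniform(0, 10, size=(n, 3))
    return FingerprintCodebook([(i, 0, 0) for i in range(n)], fps, coords)


class TestBuildCodebook:
    def test_constant_trace(self):
        cb = build_codebook(
            {(0, 0, 0): np.full((50, 3), -70.0)}, {(0, 0, 0): (1.0, 2.0, 0.0)}
        )
        assert np.allclose(cb.fingerprints[0], -70.0)
        assert np.allclose(cb.coordinates[0], [1.0, 2.0, 0.0])

    def test_noisy_trace_converges_to_mean(self, rng):
        v = -70.0 + rng.normal(0, 3.0, size=(10_000, 2))
        cb = build_codebook({(0, 0, 0): v}, {(0, 0, 0): (0, 0, 0)})
        assert np.allclose(cb.fingerprints[0], -70.0, atol=3 * 3.0 / 100)

    def test_identical_traces_distinct_coordinates(self):
        v = np.full((10, 2), -60.0)
        cb = build_codebook(
            {(0, 0, 0): v, (1, 0, 0): v},
            {(0, 0, 0): (0, 0, 0), (1, 0, 0): (5, 5, 0)},
        )
        assert np.allclose(cb.fingerprints[0], cb.fingerprints[1])
        assert not np.allclose(cb.coordinates[0], cb.coordinates[1])

    def test_silent_anchor_stored_as_floor_with_warning(self):
        v = np.full((5, 2), -60.0)
        v[:, 1] = np.nan
        with pytest.warns(UserWarning, match="never heard"):
            cb = build_codebook({(0, 0, 0): v}, {(0, 0, 0): (0, 0, 0)})
        assert cb.fingerprints[0, 1] == -100.0

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="same reference points"):
            build_codebook({(0, 0, 0): np.zeros((1, 2)) - 60}, {(1, 0, 0): (0, 0, 0)})

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FingerprintCodebook([(0, 0, 0), (0, 0, 0)], np.zeros((2, 2)), np.zeros((2, 3)))


class TestPreprocess:
    def test_one_packet_per_bin_is_identity(self):
        packets = [(0.0, 0, -60.0), (0.25, 0, -62.0), (0.5, 0, -64.0)]
        out = preprocess_test_rss(packets, n_anchors=1)
        assert np.allclose(out[:, 0], [-60.0, -62.0, -64.0])

    def test_silent_anchor_filled_with_floor(self):
        packets = [(0.0, 0, -60.0), (0.3, 0, -61.0)]
        out = preprocess_test_rss(packets, n_anchors=2)
        assert np.all(out[:, 1] == -100.0)

    def test_fast_packets_averaged_within_bin(self):
        # 8 packets at 32 Hz inside one 0.25 s bin
        times = np.arange(8) / 32.0
        values = -60.0 + np.arange(8)
        packets = [(t, 0, v) for t, v in zip(times, values)]
        out = preprocess_test_rss(packets, n_anchors=1)
        assert out.shape[0] == 1
        assert out[0, 0] == pytest.approx(values.mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="packets"):
            preprocess_test_rss([], n_anchors=2)


class TestClosestFingerprints:
    def test_exact_match_ranks_first(self, rng):
        cb = _random_codebook(rng)
        g = cb.fingerprints[7]
        idx = closest_fingerprints(cb, g, w=3)
        assert idx[0] == 7

    def test_w_equal_to_entries_returns_full_sorted_order(self, rng):
        cb = _random_codebook(rng, n=6)
        g = rng.uniform(-100, -50, size=4)
        idx = closest_fingerprints(cb, g, w=6)
        d = np.linalg.norm(cb.fingerprints - g, axis=1)
        assert np.array_equal(idx, np.argsort(d, kind="stable"))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            u = int(rng.integers(1, 8))
            w = int(rng.integers(1, n + 1))
            cb = _random_codebook(rng, n=n, u=u)
            g = rng.uniform(-100, -50, size=u)
            got = closest_fingerprints(cb, g, w)
            d = np.linalg.norm(cb.fingerprints - g, axis=1)
            want = sorted(range(n), key=lambda i: (d[i], i))[:w]
            assert np.array_equal(got, want)

    def test_ties_broken_by_insertion_order(self):
        fps = np.array([[-60.0, -60.0], [-60.0, -60.0], [-80.0, -80.0]])
        cb = FingerprintCodebook([(0, 0, 0), (1, 0, 0), (2, 0, 0)], fps, np.zeros((3, 3)))
        idx = closest_fingerprints(cb, np.array([-60.0, -60.0]), w=2)
        assert idx.tolist() == [0, 1]

    def test_w_out_of_range_rejected(self, rng):
        cb = _random_codebook(rng, n=5)
        with pytest.raises(ValueError, match="W"):
            closest_fingerprints(cb, cb.fingerprints[0], w=6)


class TestPositionEstimate:
    def test_single_neighbor_is_exact(self, rng):
        cb = _random_codebook(rng)
        assert np.allclose(position_estimate(cb, [4]), cb.coordinates[4])

    def test_centroid_arithmetic(self):
        coords = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0]], dtype=float)
        cb = FingerprintCodebook([(i, 0, 0) for i in range(3)],
                                 np.zeros((3, 2)) - 60, coords)
        assert np.allclose(position_estimate(cb, [0, 1, 2]), [1.0, 1.0, 0.0])

    def test_matches_mean_oracle(self, rng):
        cb = _random_codebook(rng)
        sel = rng.choice(20, size=5, replace=False)
        assert np.allclose(position_estimate(cb, sel), cb.coordinates[sel].mean(axis=0))

    def test_estimate_in_convex_hull(self, rng):
        cb = _random_codebook(rng)
        for _ in range(20):
            sel = rng.choice(20, size=3, replace=False)
            est = position_estimate(cb, sel)
            lo = cb.coordinates[sel].min(axis=0)
            hi = cb.coordinates[sel].max(axis=0)
            assert np.all(est >= lo - 1e-12) and np.all(est <= hi + 1e-12)

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            position_estimate(_random_codebook(rng), [])


class TestEvaluate:
    def test_perfect_estimates(self, rng):
        p = rng.uniform(0, 10, size=(5, 3))
        mse, d = evaluate_localization(p, p)
        assert mse == 0.0 and np.allclose(d, 0.0)

    def test_uniform_offset(self):
        truth = np.zeros((4, 3))
        est = truth + [2.0, 0.0, 0.0]
        mse, d = evaluate_localization(est, truth)
        assert mse == pytest.approx(4.0)
        assert np.allclose(d, 2.0)

    def test_matches_direct_recomputation(self, rng):
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3))
        mse, d = evaluate_localization(a, b)
        want = np.linalg.norm(a - b, axis=1)
        assert np.allclose(d, want)
        assert mse == pytest.approx(np.mean(want**2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            evaluate_localization(np.zeros((2, 3)), np.zeros((3, 3)))


class TestNoiselessConsistency:
    def test_query_at_reference_point_is_exact_with_w1(self):
        scene = AnchorScene(
            anchors=np.array([[10.0, 10.0], [40.0, 10.0], [25.0, 40.0]]),
            params=tuple(PropagationParams(path_loss_exponent=2.5, shadowing_sd_db=0.0)
                         for _ in range(3)),
        )
        recordings, coords = {}, {}
        pts = [(x, y) for x in (5.0, 25.0, 45.0) for y in (5.0, 25.0, 45.0)]
        for k, (x, y) in enumerate(pts):
            traj = Trajectory(np.tile([[x, y]], (10, 1)))
            recordings[(k, 0, 0)] = clip_rss(simulate_rss(scene, traj, seed=0)).values
            coords[(k, 0, 0)] = (x, y, 0.0)
        cb = build_codebook(recordings, coords)
        for k, (x, y) in enumerate(pts):
            g = clip_rss(simulate_rss(scene, Trajectory(np.array([[x, y]])), seed=1)).values[0]
            idx = closest_fingerprints(cb, g, w=1)
            assert idx[0] == k
            assert np.allclose(position_estimate(cb, idx), [x, y, 0.0])

    def test_entry_permutation_only_affects_ties(self, rng):
        cb = _random_codebook(rng, n=10)
        perm = rng.permutation(10)
        cb2 = FingerprintCodebook(
            [cb.keys[i] for i in perm], cb.fingerprints[perm], cb.coordinates[perm]
        )
        g = rng.uniform(-100, -50, size=4)
        est1 = position_estimate(cb, closest_fingerprints(cb, g, 3))
        est2 = position_estimate(cb2, closest_fingerprints(cb2, g, 3))
        assert np.allclose(est1, est2)


class TestLocalizerEstimator:
    def test_sklearn_protocol(self, rng):
        cb = _random_codebook(rng)
        est = FingerprintLocalizer(w=3).fit(cb.fingerprints, cb.coordinates)
        assert est.get_params() == {"w": 3}
        pred = est.predict(cb.fingerprints[:4])
        for g, p in zip(cb.fingerprints[:4], pred):
            want = position_estimate(cb, closest_fingerprints(cb, g, 3))
            assert np.allclose(p, want)

    def test_json_round_trip(self, rng, tmp_path):
        cb = _random_codebook(rng)
        p = tmp_path / "cb.json"
        cb.to_json(p)
        back = FingerprintCodebook.from_json(p)
        assert np.allclose(back.fingerprints, cb.fingerprints)
        assert np.allclose(back.coordinates, cb.coordinates)
        assert back.keys == cb.keys
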