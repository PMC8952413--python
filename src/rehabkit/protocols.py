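"""The simulated proximity-reporting study protocol.

One protocol run: simulate a bounded random walk through the 50 m x 50 m
ten-anchor scene, train the DNN and LSTM proximity reporters on clipped,
scaled RSS with shadowing variance 7.5 dB^2 (learning rate 0.01, 400
epochs, batch 500), then evaluate both on fresh test walks at shadowing
variances 0, 5, 10 and 15 dB^2 with a 15 m vicinity radius. Shadowing
levels are quoted as variances (dB^2) throughout, matching how the study
conditions are stated; the simulator itself takes standard deviations.

The training walk is 8000 steps with 1 m step sd — long enough to cover
the whole floor — and test walks are 2000 steps. Multi-seed summaries
average the accuracy metrics over independent runs.
"""

from __future__ import annotations

import numpy as np

from .proximity import ProximityDNN, ProximityLSTM, proximity_metrics, scale_inputs
from .rss import bounded_random_walk, clip_rss, default_scene, simulate_rss, vicinity_labels

__all__ = [
    "TRAIN_SHADOWING_VAR_DB2",
    "TEST_SHADOWING_VARS_DB2",
    "VICINITY_RADIUS_M",
    "run_proximity_protocol",
    "proximity_study",
]

TRAIN_SHADOWING_VAR_DB2 = 7.5
TEST_SHADOWING_VARS_DB2 = (0.0, 5.0, 10.0, 15.0)
VICINITY_RADIUS_M = 15.0
N_TRAIN_STEPS = 8000
N_TEST_STEPS = 2000
STEP_SD_M = 1.0


def _walk_and_rss(var_db2: float, n_steps: int, walk_seed: int, rss_seed: int):
    scene = default_scene(shadowing_sd_db=float(np.sqrt(var_db2)))
    traj = bounded_random_walk(scene.bounds, n_steps, step_sd_m=STEP_SD_M, seed=walk_seed)
    trace = clip_rss(simulate_rss(scene, traj, seed=rss_seed))
    X = scale_inputs(trace)
    Y = vicinity_labels(scene, traj, radius_m=VICINITY_RADIUS_M)
    return X, Y


def run_proximity_protocol(seed: int, test_vars=TEST_SHADOWING_VARS_DB2) -> dict:
    """One full train/evaluate run; returns {variance: {"dnn": m, "lstm": m}}."""
    root = np.random.default_rng(seed)
    sub = [int(s) for s in root.integers(0, 2**31 - 1, size=4)]
    X, Y = _walk_and_rss(TRAIN_SHADOWING_VAR_DB2, N_TRAIN_STEPS, sub[0], sub[1])
    dnn = ProximityDNN(random_state=sub[2]).fit(X, Y)
    lstm = ProximityLSTM(random_state=sub[3]).fit(X, Y)
    out = {}
    for var in test_vars:
        tsub = [int(s) for s in root.integers(0, 2**31 - 1, size=2)]
        Xt, Yt = _walk_and_rss(var, N_TEST_STEPS, tsub[0], tsub[1])
        out[var] = {
            "dnn": proximity_metrics(dnn.predict(Xt), Yt),
            "lstm": proximity_metrics(lstm.predict(Xt), Yt),
        }
    return out


def proximity_study(seeds, test_vars=TEST_SHADOWING_VARS_DB2) -> dict:
    """Mean metrics over seeds: {variance: {model: {metric: mean}}}."""
    runs = [run_proximity_protocol(s, test_vars) for s in seeds]
    summary = {}
    for var in test_vars:
        summary[var] = {}
        for model in ("dnn", "lstm"):
            ms = [r[var][model] for r in runs]
            summary[var][model] = {
                "proximity": float(np.mean([m.proximity for m in ms])),
                "distance": float(np.mean([m.distance for m in ms])),
                "overall": float(np.mean([m.overall for m in ms])),
                "proximity_sd": float(np.std([m.proximity for m in ms])),
                "distance_sd": float(np.std([m.distance for m in ms])),
            }
    return summary
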