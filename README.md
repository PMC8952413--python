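# rehabkit

Building blocks for low-cost in-home rehabilitation monitoring: knowing
*where* a person is in their home, and *what their upper body is doing*,
from unobtrusive sensors.

The package implements two method families:

1. **Bluetooth RSS localization.** Fixed anchors broadcast beacon
   packets; the received signal strength (RSS, dBm) at the person's hub
   follows a log-distance path-loss model with log-normal shadowing,
   ν_u = P_t − PL_u(d0) − 10 ξ_u log₁₀(d_u/d0) + N(0, σ_u²). On top of
   this: (a) *proximity reporting* — feed-forward (DNN) and recurrent
   (LSTM) classifiers that emit a binary vector saying, per anchor,
   whether the person is within a 15 m vicinity, confining them to a
   region of interest without computing coordinates; (b) a *region
   classifier* over windowed mean RSS; (c) *fingerprint k-NN
   positioning* — reference-point mean-RSS signatures matched by
   Euclidean distance, position estimated as the centroid of the W = 3
   nearest reference coordinates.

2. **Sparse-IMU upper-body kinematics.** Three worn IMUs (pelvis and
   both forearms) drive sequence models (Seq2Seq LSTM, bidirectional
   attention variant, Transformer encoder, full Transformer) that
   predict unit-quaternion orientations for all 15 upper-body segments
   over 5-frame windows at 40 Hz, after pelvis-frame normalization
   R_PB = R_GP⁻¹·R_GB. Around the models: quaternion algebra (including
   eigenvector averaging), sensor-to-segment calibration
   R_ori = R_mvn[n]·R_dot[n]⁻¹ with cross-session quaternion-averaged
   fixed mappings, forward kinematics P_i = P_parent + R_i·X_i, and
   evaluation via the mean angular error
   θ = (360/π)·arccos(|⟨q̂, q⟩|) plus elbow/shoulder joint angles.

A synthetic-data module generates motion-capture-like ground truth
(240 Hz) and degraded standalone-IMU streams (60 Hz, mounting rotation,
drift, noise), and RSS traces along bounded random walks, so the entire
pipeline runs and is tested without any external data. The neural
networks run on a small bundled numpy autodiff stack (no GPU framework
required). See `docs/methods.md` for models, defaults and limitations.

## Worked example

Train a proximity reporter on a simulated walk through the default
50 m × 50 m ten-anchor scene and evaluate it under heavier shadowing:

```python
import numpy as np
from rehabkit import rss, proximity

# training walk at shadowing variance 7.5 dB^2
scene = rss.default_scene(shadowing_sd_db=np.sqrt(7.5))
walk  = rss.bounded_random_walk(scene.bounds, 8000, step_sd_m=1.0, seed=0)
trace = rss.clip_rss(rss.simulate_rss(scene, walk, seed=1))
X = proximity.scale_inputs(trace)                      # [0, 1] features
Y = rss.vicinity_labels(scene, walk, radius_m=15.0)    # binary reports

lstm = proximity.ProximityLSTM(random_state=0).fit(X, Y)

# fresh test walk at shadowing variance 15 dB^2
test_scene = rss.default_scene(shadowing_sd_db=np.sqrt(15.0))
test_walk  = rss.bounded_random_walk(test_scene.bounds, 2000, step_sd_m=1.0, seed=2)
test_trace = rss.clip_rss(rss.simulate_rss(test_scene, test_walk, seed=3))
m = proximity.proximity_metrics(
    lstm.predict(proximity.scale_inputs(test_trace)),
    rss.vicinity_labels(test_scene, test_walk, radius_m=15.0),
)
print(f"proximity {m.proximity:.3f}  distance {m.distance:.3f}  overall {m.overall:.3f}")
```

```
proximity 0.927  distance 0.975  overall 0.964
```

`proximity` is the fraction of truly-in-vicinity (step, anchor) pairs
correctly reported in vicinity (here 92.7%), `distance` the fraction of
truly-out pairs correctly reported out (97.5%), and `overall` their
label-weighted combination. Even at double the training shadowing
variance, the recurrent reporter keeps both error types in the
single-digit percent range by exploiting the temporal continuity of the
walk.

The kinematics half runs the same way from synthetic data:

```python
from rehabkit import synthetic_motion as sm, motion_models as mm, motion_eval, quat

X, Y, _ = sm.make_training_corpus(1, sm.MotionGenConfig(duration_s=6.25), seed=42)
est = mm.MotionInferenceRegressor(architecture="transformer_encoder",
                                  epochs=200, tol=0.008, random_state=0).fit(X, Y)
truth = Y.reshape(len(Y), 5, 15, 4)
ang = quat.angle_between(est.predict(X), truth).mean()
print(f"training-window mean angular error: {ang:.2f} deg")
```

```
training-window mean angular error: 1.38 deg
```

Fifty windows are enough for every architecture to overfit to a couple
of degrees — a capacity check, not a generalization claim.

A command-line interface wraps the library for shell use
(`rehabkit --help`): `simulate-rss`, `train-proximity`,
`eval-proximity`, `classify-roi`, `build-codebook`, `locate`,
`generate-motion`, `calibrate`, `train-motion`, `infer-motion`,
`evaluate-motion`. Every run logs its config hash and seed and writes
into a run directory.

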