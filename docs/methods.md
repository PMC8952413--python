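# Methods

`rehabkit` bundles two method families for in-home rehabilitation
monitoring: Bluetooth received-signal-strength (RSS) localization, and
upper-body kinematics inference from three sparse inertial measurement
units (IMUs). This note records the models, their assumptions, the
defaults that matter, and what the synthetic data does and does not
establish.

## RSS propagation model

The RSS (dBm) received from anchor *u* at distance *d_u* follows the
log-distance model with log-normal shadowing:

    nu_u = P_t − PL_u(d0) − 10 ξ_u log10(d_u / d0) + X_u,
    X_u ~ N(0, σ_u²)

with transmit power `P_t`, reference path loss `PL_u(d0)` at `d0 = 1 m`
(the universal convention), per-anchor path-loss exponent `ξ_u`, and
shadowing standard deviation `σ_u` (dB). Receivers clip reported values
into [−100, −50] dBm; classifier features rescale that range onto
[0, 1]. Shadowing realizations are i.i.d. across anchors and time
steps — temporal correlation in the features comes from the target's
continuous trajectory, not from the noise.

**Default scene.** A 50 m × 50 m floor divided into ten subcenters
(5 columns × 2 rows) with one anchor at the middle of each. Per-anchor
parameters use `P_t − PL(d0) = −50 dBm` — the mean RSS meets the
clipping ceiling exactly at the reference distance — and exponents
spread over 2.1–3.0, covering near-free-space to cluttered indoor
conditions. These per-anchor values are this package's own defaults,
chosen once from typical Bluetooth-low-energy indoor figures.

**Shadowing units.** Study-protocol shadowing levels are quoted as
*variances* in dB² (training 7.5 dB², test sweep 0–15 dB², i.e. sd up to
√15 ≈ 3.9 dB). The simulator API takes standard deviations;
`rehabkit.protocols` converts. The variance reading is the one under
which the reported proximity accuracies are information-theoretically
attainable: with the same numbers read as standard deviations, the
Bayes-optimal single-frame classifier already falls far short of them.

## Proximity reporting

A proximity report is a binary vector over anchors: entry *u* is 1 iff
the target is within the vicinity radius (15 m, boundary inclusive) of
anchor *u*. This is multi-label classification; the loss is per-anchor
binary cross-entropy (including the (1−y) term), summed over anchors and
averaged over the batch.

* **DNN**: inputs (U scaled RSS values) → two ReLU hidden layers of 12
  units → U sigmoid outputs. Memoryless.
* **LSTM**: a sliding window of the 5 most recent RSS vectors (the trace
  is edge-padded so every step gets a report) through one LSTM layer of
  32 units; the final hidden state feeds the output layer. The window
  length is this package's default: 0.5 s of context at the 10 Hz beacon
  rate, enough for the temporal averaging that gives the recurrent model
  its advantage while keeping the desk-scale protocol fast.
* Decision rule: predict 1 iff the output probability strictly exceeds
  0.5 (a tie at exactly 0.5 classifies as 0).
* Training: plain SGD, learning rate 0.01, 400 epochs, batch 500,
  training shadowing variance 7.5 dB². Training walks are 8000 steps
  (step sd 1 m, reflective at the walls), long enough to cover the full
  floor; test walks are 2000 steps. Walk length and step size are
  package choices — coverage of the floor during training is what makes
  the learned reports transfer to unseen walks.

Metrics: *proximity accuracy* (fraction of truly-in-vicinity
(step, anchor) pairs reported 1), *distance accuracy* (fraction of
truly-out pairs reported 0), and *overall accuracy*, which satisfies the
exact identity overall = (n₊·proximity + n₋·distance)/(n₊+n₋).

The region-of-interest (RoI) variant classifies windowed mean RSS
(0.5 s windows) into one of K regions with a 3-layer LSTM and softmax
head. Its optimizer is AdamW (lr 0.001): a three-layer recurrent stack
makes no training progress under plain SGD at these problem sizes,
whereas the single-layer binary reporters keep the prescribed SGD.

## Fingerprint k-NN localization

Training records ~minutes of RSS at each reference point of a room grid
and stores the time-mean vector (the fingerprint) with the point's 3D
coordinates. Codebook fingerprints are clipped like test features, for
consistency. At test time packets are averaged into 0.25 s bins (4 Hz);
anchors silent within a bin carry ν_min = −100 dBm (coinciding with the
clipping floor). Matching minimizes the Euclidean norm between the test
fingerprint and each codebook entry; ties break by codebook insertion
order (deterministic). The position estimate is the centroid of the
W = 3 nearest reference coordinates, so it always lies in their convex
hull; W = 1 returns a reference point exactly. Localization error is
reported as mean squared Euclidean distance plus per-point distances.

## Rotation algebra

Quaternions are scalar-first `[w, x, y, z]`, renormalized after every
operation (unit norm preserved to well below 1e-9 over long chains).
`q` and `−q` encode the same rotation; every angle uses the absolute
inner product and is therefore sign-invariant. The inter-orientation
angle is

    θ = (360/π) · arccos(clamp(|⟨a, b⟩|, 0, 1))  ∈ [0°, 180°]

the standard relative-rotation angle. Averaging a set of orientations
uses the eigenvector method: the unit eigenvector of Σᵢ qᵢqᵢᵀ with the
largest eigenvalue, which is invariant to per-input sign flips. Mean
angular error averages per-pair angles (after the arccos), over all
frames and segments.

## Skeleton and forward kinematics

The upper body is modelled as 15 segments (pelvis→spine→neck→head plus
shoulder→upper-arm→forearm→hand on each side), a tree rooted at the
pelvis with parents preceding children. Each non-root segment carries a
fixed local offset vector; the bundled neutral skeleton (straight spine,
arms down, plausible metre-scale adult lengths) stands in for
per-participant segment lengths and is overridable via JSON. Global
frame is right-handed, Z-up, +x forward.

Forward kinematics walks the tree: `P_i = P_parent(i) + R_i · X_i` from
a configurable root position. It is translation-equivariant and keeps
each child endpoint exactly `|X_i|` from its parent for any pose.

Pelvis ("root") normalization removes global heading:
`R_PB = R_GP⁻¹ R_GB` for orientations and `ā = R_GP⁻¹ a` for
acceleration vectors; denormalization is its exact inverse. Whether
gravity is present in the acceleration channel is a property of the data
source; the transforms act on vectors as given, and the synthetic
generator makes gravity explicit via a flag.

## Sparse-IMU motion inference

The task is sequence-to-sequence: five frames (0.125 s at 40 Hz) of
pelvis-normalized orientation + acceleration from three segments
(pelvis, right forearm, left forearm; 21 features per frame) predict the
normalized orientations of all 15 segments over the same five frames (60
quaternion components per frame). 240 Hz sequences are cut into
non-overlapping 30-frame windows decimated by 6. Features and targets
are standardized with training-set statistics only (zero-variance
features pass through with sd clamped to 1); frozen statistics apply to
validation and test data.

Four drop-in interchangeable architectures:

1. **Seq2Seq** — LSTM encoder (hidden 512); the decoder LSTM starts from
   the encoder's final state and consumes that state's hidden vector at
   every step (the decoder input is otherwise unspecified in this
   framing; feeding the summary state is the simplest non-autoregressive
   choice).
2. **Seq2Seq (BiRNN, attention)** — bidirectional encoder; each decoder
   step attends over encoder outputs with additive (Bahdanau) attention.
3. **Transformer encoder** — embedding width 84 (the smallest multiple
   of the 21 attention heads ≥ 64), 2 layers, feedforward 200,
   sinusoidal positional encoding, linear head per frame.
4. **Transformer full** — encoder-decoder, width 64, 4 heads, 4 layers,
   feedforward 2048; the decoder is non-autoregressive, driven by a
   learned per-position query plus positional encoding, with
   cross-attention to the encoder memory.

Training minimizes the mean absolute error over raw quaternion
components (averaged over frames, segments and the 4 components),
computed on the de-standardized scale, under AdamW with learning rate
0.001 (betas 0.95/0.99 for the transformers, 0.9/0.999 otherwise),
dropout 0.1, batch 32. Predictions are renormalized to unit quaternions
per segment and frame after the linear output layer. Seeded training is
bit-reproducible on one device.

All networks run on a small in-package numpy stack: a reverse-mode
autodiff engine plus layers (the LSTM cell is a single fused graph node
with a hand-written vectorized backward pass using single-precision
internals) and SGD/AdamW optimizers, verified against numerical
differentiation in the test suite.

## Sensor-to-segment calibration

A standalone IMU's reference frame differs from the capture convention
by a rotation assumed fixed within a recording session. From one
synchronized frame *n*:

    R_ori = R_mvn_seg[n] · R_dot_raw[n]⁻¹     (orientation map)
    R_acc = R_mvn_sens[n] · R_dot_raw[n]⁻¹    (acceleration map)

applied to the whole session by left-multiplying orientations and
rotating acceleration vectors. The acceleration map uses the capture
system's *sensor* orientation at *n*, taken literally. When the offset
is truly fixed, recovery is exact (≤1e-6°) at every frame and the map is
independent of *n*; under drift, the applied error grows away from the
calibration frame. Translational lever-arm effects between sensor sites
are not corrected.

Defaults: the calibration frame is the most quasi-static one (minimum
smoothed acceleration magnitude) rather than an arbitrary frame —
exactness is n-invariant anyway, and this reduces sensitivity to
dynamics when noise or drift is present. Synchronization resamples both
streams to 40 Hz (linear interpolation with hemisphere-continuity
correction, then renormalization) and aligns them by maximizing the
cross-correlation of mean-removed acceleration magnitude — an
automatable stand-in for manually aligning on a deliberate bump; if no
distinctive event exists the offset falls back to 0 with a warning.

The *fixed* (cross-session) mapping is the quaternion eigenvector
average of the per-session maps (orientation and acceleration maps
averaged separately). Its applied error is bounded by the largest
angular spread among session maps. Continuous/online recalibration is
out of scope.

## Joint angles and evaluation

A joint angle is the relative-rotation angle between the two segments
flanking the joint: elbow = upper arm vs forearm (0° = straight arm),
shoulder = T8 vs upper arm. The shoulder's three degrees of freedom are
deliberately collapsed into one angle. Joint angles are invariant to
global rotation of the whole pose. The signed joint-angle error is
*inferred minus truth*, so negative values mean the inferred angle was
more acute. Histograms use fixed-width bins and conserve sample counts.

## Synthetic motion generator

Ground-truth streams are a band-limited random walk on rotations: white
angular-velocity noise per segment, low-passed at 1.5 Hz (second-order
Butterworth, zero-phase), rescaled so per-frame angular speed never
exceeds 90°/s, integrated at 240 Hz. Accelerations are second
differences of forward-kinematics endpoint positions (+ gravity when
flagged), in the global frame; sensor orientation is taken equal to
segment orientation in synthetic data. The standalone-IMU emulation
left-multiplies a reference-frame offset `drift(t) ∘ mounting` onto the
orientations, re-expresses accelerations in the same offset frame, adds
Gaussian orientation/acceleration noise, and decimates to 60 Hz.

This is *not* physically realistic human movement: there are no joint
limits, no task structure, no contact events, and its pose distribution
is far narrower than daily-living motion. Passing tests therefore
establish that the pipeline's transforms, training loops, calibration
algebra and metrics are correct and mutually consistent — not that the
learned models would reach any particular accuracy on real recordings.
Desk-scale corpora (tens of windows) demonstrate capacity by
overfitting, not generalization.

## Numerical choices and degenerate inputs

- Quaternion norms are validated to 1e-6 on file ingest and renormalized
  internally; zero quaternions are rejected.
- `from_matrix` rejects matrices off the rotation manifold beyond 1e-6
  and reports the measured deviation.
- Distances below the propagation reference distance are floored at d0
  with a warning; vicinity boundaries are inclusive.
- Zero-variance features standardize with sd clamped to 1 (warning);
  sequences shorter than one window yield empty window sets (warning);
  k-NN ties break by insertion order; empty inputs are rejected with
  named errors.
- All randomness flows from `numpy.random.default_rng` seeds; training
  is deterministic given the seed on one device.

## Problem sizes used by the bundled study scripts

The proximity study trains on 8000-step walks and evaluates 2000-step
walks over 10 seeds; capacity checks use 50 windows (6.25 s of 240 Hz
motion) and at most 200 epochs. These sizes are the package's chosen
desk-scale study conditions.

## Known limitations

- The per-anchor propagation table is a package default, not a measured
  site survey; absolute accuracies depend on it.
- The LSTM proximity reporter sees a fixed 5-step context; very slow
  shadowing dynamics would favour longer memories.
- Calibration assumes a rigid, session-constant sensor offset; drift is
  emulated and measured but not corrected.
- The motion models are trained and evaluated on synthetic motion only;
  no claim is made about accuracy on real IMU recordings.

*Implementation note:* the inter-orientation angle is evaluated in the
equivalent atan2 form on the difference rotation (sin and cos of θ/2
from `a⁻¹b`), which keeps zero angles exact to machine precision where
the arccos form loses half its significant digits.
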