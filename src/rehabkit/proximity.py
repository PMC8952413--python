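"""Neural proximity reporting: is the target within range of each anchor?

Given a clipped RSS vector (one value per anchor, scaled into [0, 1]),
the classifiers emit a binary proximity report per anchor — a
multi-label problem, one label per anchor. Two estimators are provided:
a plain feed-forward network (:class:`ProximityDNN`) and a recurrent
:class:`ProximityLSTM` that consumes a short window of consecutive RSS
vectors, exploiting the temporal correlation induced by the target's
trajectory. A K-way region-of-interest classifier
(:class:`RoIClassifier`) maps windowed mean RSS to one of K regions.

All three follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params``) and are bit-reproducible given
``random_state``. The binary reporters train per-anchor binary
cross-entropy with plain SGD; the region classifier trains categorical
cross-entropy with AdamW (a three-layer recurrent stack makes no
progress under plain SGD at these problem sizes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn.autodiff import Tensor
from .nn.layers import LSTM, Linear, Module
from .nn.optim import AdamW, SGD
from .rss import RSS_CEIL, RSS_FLOOR, RSSTrace

__all__ = [
    "scale_inputs",
    "ProximityDNN",
    "ProximityLSTM",
    "RoIClassifier",
    "ProximityMetrics",
    "proximity_metrics",
    "window_mean_rss",
]


def scale_inputs(trace: RSSTrace | np.ndarray) -> np.ndarray:
    """Affine map of clipped RSS from [-100, -50] dBm onto [0, 1]."""
    values = trace.values if isinstance(trace, RSSTrace) else np.asarray(trace, dtype=float)
    if np.any(values < RSS_FLOOR) or np.any(values > RSS_CEIL):
        raise ValueError("inputs must be clipped to [-100, -50] dBm first (see clip_rss)")
    return (values - RSS_FLOOR) / (RSS_CEIL - RSS_FLOOR)


@dataclass(frozen=True)
class ProximityMetrics:
    """Accuracy decomposition of a proximity report.

    ``proximity`` counts correct in-vicinity detections among true
    positives; ``distance`` counts correct out-of-vicinity detections
    among true negatives; ``overall`` is the label-weighted combination
    of the two (fraction correct over all (step, anchor) pairs).
    Undefined components (no positive or no negative ground truth) are
    NaN.
    """

    proximity: float
    distance: float
    overall: float


def proximity_metrics(pred: np.ndarray, truth: np.ndarray) -> ProximityMetrics:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    pos = truth == 1
    neg = truth == 0
    prox = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    dist = float(np.mean(pred[neg] == 0)) if neg.any() else float("nan")
    overall = float(np.mean(pred == truth))
    return ProximityMetrics(proximity=prox, distance=dist, overall=overall)


class _MLP(Module):
    def __init__(self, rng, n_in, hidden, n_out):
        super().__init__()
        dims = [n_in, *hidden, n_out]
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for lay in self.layers[:-1]:
            x = lay(x).relu()
        return self.layers[-1](x)


def _bce_loss(logits: Tensor, y: np.ndarray) -> Tensor:
    """Per-anchor binary cross-entropy, summed over anchors, mean over batch."""
    p = logits.sigmoid()
    yt = Tensor(y)
    eps = 1e-9
    ll = yt * (p + eps).log() + (1.0 - yt) * (1.0 - p + eps).log()
    return -ll.sum(axis=-1).mean()


class _ProximityBase(BaseEstimator, ClassifierMixin):
    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_steps, n_anchors)")
        if np.any(X < 0) or np.any(X > 1):
            raise ValueError("features must be scaled to [0, 1] (see scale_inputs)")
        return X

    def predict(self, X) -> np.ndarray:
        """Binary proximity reports; a probability of exactly 0.5 maps to 0."""
        check_is_fitted(self, "model_")
        return (self.predict_proba(X) > self.threshold).astype(int)


class ProximityDNN(_ProximityBase):
    """Feed-forward proximity reporter (ReLU MLP, sigmoid outputs).

    Parameters follow the simulation training protocol: learning rate
    0.01, 400 epochs, batch size 500, two hidden layers of 12 units.
    """

    def __init__(self, hidden=(12, 12), lr=0.01, epochs=400, batch_size=500,
                 threshold=0.5, random_state=None):
        self.hidden = hidden
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, Y):
        X = self._check_X(X)
        Y = np.asarray(Y, dtype=float)
        if Y.shape != X.shape:
            raise ValueError("Y must align with X, one binary label per anchor")
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.model_ = _MLP(rng, X.shape[1], tuple(self.hidden), X.shape[1])
        opt = SGD(self.model_.parameters(), lr=self.lr)
        self.loss_history_ = _train_loop(
            self.model_, opt, X, Y, self.epochs, self.batch_size, rng,
            forward=lambda m, xb: m(Tensor(xb)),
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        logits = self.model_(Tensor(X))
        return 1.0 / (1.0 + np.exp(-logits.data))


class ProximityLSTM(_ProximityBase):
    """Recurrent proximity reporter over sliding RSS windows.

    Each prediction consumes the ``memory`` most recent RSS vectors
    (edge-padded at the start of the trace so every step gets a report)
    through a single LSTM layer; the final hidden state feeds a linear
    output layer with sigmoid activations.
    """

    def __init__(self, hidden=32, memory=5, lr=0.01, epochs=400, batch_size=500,
                 threshold=0.5, random_state=None):
        self.hidden = hidden
        self.memory = memory
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.random_state = random_state

    def _windows(self, X: np.ndarray) -> np.ndarray:
        pad = np.repeat(X[:1], self.memory - 1, axis=0)
        Xp = np.concatenate([pad, X], axis=0)
        idx = np.arange(self.memory)[None, :] + np.arange(X.shape[0])[:, None]
        return Xp[idx]  # (T, memory, U)

    def fit(self, X, Y):
        X = self._check_X(X)
        Y = np.asarray(Y, dtype=float)
        if Y.shape != X.shape:
            raise ValueError("Y must align with X, one binary label per anchor")
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.model_ = _LSTMNet(rng, X.shape[1], self.hidden, X.shape[1])
        opt = SGD(self.model_.parameters(), lr=self.lr)
        W = self._windows(X)
        self.loss_history_ = _train_loop(
            self.model_, opt, W, Y, self.epochs, self.batch_size, rng,
            forward=lambda m, xb: m(Tensor(xb)),
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        logits = self.model_(Tensor(self._windows(X)))
        return 1.0 / (1.0 + np.exp(-logits.data))


class _LSTMNet(Module):
    def __init__(self, rng, n_in, hidden, n_out, n_layers=1):
        super().__init__()
        dims = [n_in] + [hidden] * n_layers
        self.rnns = [LSTM(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.out = Linear(rng, hidden, n_out)

    def __call__(self, x: Tensor) -> Tensor:
        h = None
        for rnn in self.rnns:
            x, (h, _) = rnn(x)
        return self.out(h)


def _train_loop(model, opt, X, Y, epochs, batch_size, rng, forward):
    n = X.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            sel = order[lo : lo + batch_size]
            model.zero_grad()
            loss = _bce_loss(forward(model, X[sel]), Y[sel])
            if not np.isfinite(loss.data):
                raise FloatingPointError("training loss is not finite; aborting")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return np.array(history)


def window_mean_rss(values: np.ndarray, step_interval_s: float, window_s: float = 0.5):
    """Mean RSS over consecutive windows of ``window_s`` seconds.

    Returns ``(means, window_index)`` where ``window_index[t]`` maps each
    retained step to its window. Incomplete trailing windows are dropped.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    k = int(round(window_s / step_interval_s))
    if k < 1:
        raise ValueError("window shorter than one step")
    n = (values.shape[0] // k) * k
    if n == 0:
        raise ValueError("trace shorter than one window")
    means = values[:n].reshape(-1, k, values.shape[1]).mean(axis=1)
    return means, np.repeat(np.arange(means.shape[0]), k)


class RoIClassifier(BaseEstimator, ClassifierMixin):
    """Region-of-interest classifier: 3-layer LSTM over windowed mean RSS.

    Input features are the per-anchor mean RSS over consecutive 0.5 s
    windows (see :func:`window_mean_rss`); the output is one of K region
    labels per window via a softmax head.
    """

    def __init__(self, hidden=32, n_layers=3, memory=10, lr=0.001, epochs=200,
                 batch_size=128, random_state=None):
        self.hidden = hidden
        self.n_layers = n_layers
        self.memory = memory
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _windows(self, X):
        pad = np.repeat(X[:1], self.memory - 1, axis=0)
        Xp = np.concatenate([pad, X], axis=0)
        idx = np.arange(self.memory)[None, :] + np.arange(X.shape[0])[:, None]
        return Xp[idx]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        onehot = np.eye(K)[y_idx]
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.model_ = _LSTMNet(rng, X.shape[1], self.hidden, K, n_layers=self.n_layers)
        # a three-layer recurrent stack trains poorly under plain SGD;
        # use AdamW here (the binary proximity reporters keep SGD)
        opt = AdamW(self.model_.parameters(), lr=self.lr)

        def forward_ce(m, xb):
            return m(Tensor(xb))

        n = X.shape[0]
        W = self._windows(X)
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                sel = order[lo : lo + self.batch_size]
                self.model_.zero_grad()
                logits = forward_ce(self.model_, W[sel])
                logp = (logits.softmax(axis=-1) + 1e-9).log()
                loss = -(Tensor(onehot[sel]) * logp).sum(axis=-1).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError("training loss is not finite; aborting")
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        self.loss_history_ = np.array(history)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        logits = self.model_(Tensor(self._windows(X)))
        return self.classes_[np.argmax(logits.data, axis=-1)]

    def confusion_matrix(self, X, y) -> np.ndarray:
        """Rows = true region, columns = predicted region (class order)."""
        pred = self.predict(X)
        y = np.asarray(y)
        K = len(self.classes_)
        cm = np.zeros((K, K), dtype=int)
        lut = {c: i for i, c in enumerate(self.classes_)}
        for t, p in zip(y, pred):
            cm[lut[t], lut[p]] += 1
        return cm
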