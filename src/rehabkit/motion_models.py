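"""Sparse-to-full upper-body motion inference.

Frames the task as sequence-to-sequence regression: five frames (0.125 s
at 40 Hz) of pelvis-normalized orientation quaternions and accelerations
from three sparse segments (pelvis, right forearm, left forearm; 21
features per frame) predict the normalized orientations of all fifteen
upper-body segments over the same five frames (60 quaternion components
per frame).

Windows are cut from 240 Hz sequences as non-overlapping blocks of 30
raw frames decimated by 6. Features are standardized with training-set
statistics only. Four interchangeable architectures are provided —
an LSTM encoder-decoder (Seq2Seq), a bidirectional variant with additive
attention, a Transformer encoder, and a full encoder-decoder Transformer
— all trained with mean-absolute-error loss on the raw quaternion
components under AdamW (learning rate 0.001). Predictions are
renormalized to unit quaternions per segment and frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn.autodiff import Tensor, concat, stack
from .nn.layers import (
    LSTM,
    BahdanauAttention,
    BiLSTM,
    Dropout,
    Linear,
    Module,
    TransformerDecoderLayer,
    TransformerEncoderLayer,
    positional_encoding,
)
from .nn.optim import AdamW
from .skeleton import PoseSequence, SEGMENT_NAMES

__all__ = [
    "ARCHITECTURES",
    "INPUT_SEGMENTS",
    "ModelConfig",
    "StandardizationStats",
    "build_windows",
    "fit_standardization",
    "apply_standardization",
    "invert_standardization",
    "MotionInferenceRegressor",
    "train_model",
    "predict_upper_body",
]

ARCHITECTURES = ("seq2seq", "seq2seq_birnn_attn", "transformer_encoder", "transformer_full")

#: Sparse input segments: the three worn-sensor sites.
INPUT_SEGMENTS = ("Pelvis", "RightForearm", "LeftForearm")

_N_IN = len(INPUT_SEGMENTS) * 7  # 4 quaternion + 3 acceleration per segment
_N_OUT = len(SEGMENT_NAMES) * 4


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults: batch 32, raw sequence length 30 at 240 Hz, downsample 6
    (five model frames at 40 Hz), stride 30 (non-overlapping), equal
    input/output length. Recurrent models use hidden size 512; the
    Transformer encoder uses 21 heads / 2 layers / feedforward 200, and
    the full Transformer 4 heads / 4 layers / feedforward 2048, both
    with Adam betas (0.95, 0.99). Dropout 0.1, AdamW learning rate 0.001.
    """

    architecture: str = "seq2seq"
    batch_size: int = 32
    seq_len_raw: int = 30
    downsample: int = 6
    in_out_ratio: int = 1
    stride: int = 30
    hidden_size: int = 512
    n_heads: int | None = None
    n_layers: int | None = None
    ff_size: int | None = None
    dropout: float = 0.1
    epochs: int = 200
    lr: float = 0.001
    betas: tuple | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}")
        for name in ("batch_size", "seq_len_raw", "downsample", "stride", "hidden_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        defaults = {
            "transformer_encoder": {"n_heads": 21, "n_layers": 2, "ff_size": 200, "betas": (0.95, 0.99)},
            "transformer_full": {"n_heads": 4, "n_layers": 4, "ff_size": 2048, "betas": (0.95, 0.99)},
        }.get(self.architecture, {"betas": (0.9, 0.999)})
        for k, v in defaults.items():
            if getattr(self, k) is None:
                object.__setattr__(self, k, v)

    @property
    def n_model_frames(self) -> int:
        return self.seq_len_raw // self.downsample

    @property
    def embed_dim(self) -> int:
        """Transformer width: smallest multiple of the head count >= 64."""
        h = self.n_heads or 1
        return max(64 + (-64) % h, h)


@dataclass(frozen=True)
class StandardizationStats:
    """Per-feature mean/sd of inputs and targets (training split only)."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray


def build_windows(seq: PoseSequence, cfg: ModelConfig = ModelConfig()):
    """Cut a pelvis-normalized 240 Hz sequence into model windows.

    Returns ``(X, Y)``: inputs (N, 5, 21) from the sparse segments and
    targets (N, 5, 60) covering all fifteen segments. Sequences shorter
    than one window yield empty arrays with a warning.
    """
    if seq.frame != "pelvis-normalized":
        raise ValueError("sequence must be pelvis-normalized before windowing")
    if seq.accelerations is None:
        raise ValueError("sequence must carry accelerations")
    m = cfg.n_model_frames
    T = seq.n_frames
    n_win = (T - cfg.seq_len_raw) // cfg.stride + 1 if T >= cfg.seq_len_raw else 0
    if n_win <= 0:
        warnings.warn(f"sequence of {T} frames is shorter than one window", stacklevel=2)
        return np.empty((0, m, _N_IN)), np.empty((0, m, _N_OUT))
    in_idx = [seq.segments.index(s) for s in INPUT_SEGMENTS]
    out_idx = [seq.segments.index(s) for s in SEGMENT_NAMES]
    X = np.empty((n_win, m, _N_IN))
    Y = np.empty((n_win, m, _N_OUT))
    for w in range(n_win):
        lo = w * cfg.stride
        frames = lo + np.arange(m) * cfg.downsample
        q_in = seq.orientations[frames][:, in_idx, :]  # (m, 3, 4)
        a_in = seq.accelerations[frames][:, in_idx, :]  # (m, 3, 3)
        X[w] = np.concatenate([q_in, a_in], axis=-1).reshape(m, _N_IN)
        Y[w] = seq.orientations[frames][:, out_idx, :].reshape(m, _N_OUT)
    return X, Y


def fit_standardization(X: np.ndarray, Y: np.ndarray) -> StandardizationStats:
    """Per-feature statistics over all training windows and frames.

    Zero-variance features get a unit sd (with a warning) so they pass
    through unscaled.
    """
    if len(X) == 0:
        raise ValueError("cannot fit standardization on an empty training set")

    def stats(a):
        flat = a.reshape(-1, a.shape[-1])
        mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        if np.any(std == 0):
            warnings.warn(
                f"zero-variance feature(s) {np.flatnonzero(std == 0).tolist()}; sd clamped to 1",
                stacklevel=3,
            )
            std = np.where(std == 0, 1.0, std)
        return mean, std

    xm, xs = stats(X)
    ym, ys = stats(Y)
    return StandardizationStats(xm, xs, ym, ys)


def apply_standardization(stats: StandardizationStats, X=None, Y=None):
    out = []
    if X is not None:
        out.append((np.asarray(X) - stats.x_mean) / stats.x_std)
    if Y is not None:
        out.append((np.asarray(Y) - stats.y_mean) / stats.y_std)
    return out[0] if len(out) == 1 else tuple(out)


def invert_standardization(stats: StandardizationStats, Xs=None, Ys=None):
    out = []
    if Xs is not None:
        out.append(np.asarray(Xs) * stats.x_std + stats.x_mean)
    if Ys is not None:
        out.append(np.asarray(Ys) * stats.y_std + stats.y_mean)
    return out[0] if len(out) == 1 else tuple(out)


# ---------------------------------------------------------------------------
# Architectures. All consume standardized (B, m, 21) windows and emit
# standardized (B, m, 60) predictions; drop-in interchangeable.
# ---------------------------------------------------------------------------


class _Seq2Seq(Module):
    """LSTM encoder-decoder. The decoder starts from the encoder's final
    state and consumes that state's hidden vector at every step."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        H = cfg.hidden_size
        self.enc = LSTM(rng, _N_IN, H)
        self.dec = LSTM(rng, H, H)
        self.head = Linear(rng, H, _N_OUT)
        self.drop = Dropout(cfg.dropout)
        self.m = cfg.n_model_frames

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        _, (h, c) = self.enc(x)
        B = x.shape[0]
        dec_in = stack([h] * self.m, axis=1)  # (B, m, H)
        out, _ = self.dec(self.drop(dec_in, rng), (h, c))
        return self.head(self.drop(out, rng))


class _Seq2SeqAttn(Module):
    """Bidirectional LSTM encoder with additive (Bahdanau) attention
    decoding: each step attends over encoder outputs with the current
    decoder hidden state."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        H = cfg.hidden_size
        self.enc = BiLSTM(rng, _N_IN, H)
        self.attn = BahdanauAttention(rng, 2 * H, H, H)
        self.dec = LSTM(rng, 2 * H, H)
        self.head = Linear(rng, H, _N_OUT)
        self.drop = Dropout(cfg.dropout)
        self.m = cfg.n_model_frames

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        enc_out, (hf, cf, hb, cb) = self.enc(x)
        enc_out = self.drop(enc_out, rng)
        h, c = hf, cf
        outs = []
        for _ in range(self.m):
            ctx = self.attn(h, enc_out)  # (B, 2H)
            step, (h, c) = self.dec(ctx.reshape(ctx.shape[0], 1, -1), (h, c))
            outs.append(step[:, 0, :])
        return self.head(self.drop(stack(outs, axis=1), rng))


class _TransformerEncoder(Module):
    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        E = cfg.embed_dim
        self.embed = Linear(rng, _N_IN, E)
        self.pe = Tensor(positional_encoding(cfg.n_model_frames, E))
        self.blocks = [
            TransformerEncoderLayer(rng, E, cfg.n_heads, cfg.ff_size, cfg.dropout)
            for _ in range(cfg.n_layers)
        ]
        self.head = Linear(rng, E, _N_OUT)

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        z = self.embed(x) + self.pe
        for blk in self.blocks:
            z = blk(z, rng)
        return self.head(z)


class _TransformerFull(Module):
    """Encoder-decoder Transformer decoded non-autoregressively: the
    decoder input is a learned per-position query plus positional
    encoding, attending to the encoder memory."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        E = cfg.embed_dim
        m = cfg.n_model_frames
        self.embed = Linear(rng, _N_IN, E)
        self.pe = Tensor(positional_encoding(m, E))
        self.query = Tensor(rng.normal(0.0, 0.02, size=(m, E)), requires_grad=True)
        self.enc_blocks = [
            TransformerEncoderLayer(rng, E, cfg.n_heads, cfg.ff_size, cfg.dropout)
            for _ in range(cfg.n_layers)
        ]
        self.dec_blocks = [
            TransformerDecoderLayer(rng, E, cfg.n_heads, cfg.ff_size, cfg.dropout)
            for _ in range(cfg.n_layers)
        ]
        self.head = Linear(rng, E, _N_OUT)

    def __call__(self, x: Tensor, rng=None) -> Tensor:
        mem = self.embed(x) + self.pe
        for blk in self.enc_blocks:
            mem = blk(mem, rng)
        z = self.query + self.pe
        z = stack([z] * x.shape[0], axis=0) if z.ndim == 2 else z
        for blk in self.dec_blocks:
            z = blk(z, mem, rng)
        return self.head(z)


_ARCH_CLASSES = {
    "seq2seq": _Seq2Seq,
    "seq2seq_birnn_attn": _Seq2SeqAttn,
    "transformer_encoder": _TransformerEncoder,
    "transformer_full": _TransformerFull,
}


class MotionInferenceRegressor(BaseEstimator, RegressorMixin):
    """Sequence model predicting 15-segment orientations from 3 sparse sensors.

    ``fit`` consumes raw (unstandardized) windows ``X (N, m, 21)`` and
    quaternion targets ``Y (N, m, 60)``; standardization statistics are
    fitted on the training set and frozen. The training loss is the mean
    absolute error over raw quaternion components; ``predict`` returns
    unit-renormalized quaternions of shape (N, m, 15, 4).
    """

    def __init__(self, architecture="seq2seq", epochs=200, lr=0.001, batch_size=32,
                 hidden_size=512, dropout=0.1, tol=None, random_state=None):
        self.architecture = architecture
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.hidden_size = hidden_size
        self.dropout = dropout
        self.tol = tol
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            architecture=self.architecture, epochs=self.epochs, lr=self.lr,
            batch_size=self.batch_size, hidden_size=self.hidden_size,
            dropout=self.dropout,
        )

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 3 or X.shape[-1] != _N_IN:
            raise ValueError(f"X must be (N, m, {_N_IN})")
        if Y.shape != X.shape[:2] + (_N_OUT,):
            raise ValueError(f"Y must be (N, m, {_N_OUT}) aligned with X")
        if len(X) == 0:
            raise ValueError("need at least one training window")
        cfg = self._config()
        rng = np.random.default_rng(self.random_state)
        self.stats_ = fit_standardization(X, Y)
        self.model_ = _ARCH_CLASSES[cfg.architecture](rng, cfg)
        opt = AdamW(self.model_.parameters(), lr=cfg.lr, betas=cfg.betas)
        Xs = apply_standardization(self.stats_, X=X)
        ym = Tensor(self.stats_.y_mean)
        ys = Tensor(self.stats_.y_std)
        n = len(X)
        history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for lo in range(0, n, cfg.batch_size):
                sel = order[lo : lo + cfg.batch_size]
                self.model_.zero_grad()
                pred_std = self.model_(Tensor(Xs[sel]), rng=rng)
                pred_raw = pred_std * ys + ym
                loss = (pred_raw - Tensor(Y[sel])).abs().mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        "training loss is not finite; lower the learning rate or "
                        "check the input scaling"
                    )
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                weights.append(len(sel))
            history.append(float(np.average(losses, weights=weights)))
            if self.tol is not None and history[-1] < self.tol:
                break
        self.loss_history_ = np.array(history)
        self.n_features_in_ = _N_IN
        return self

    def predict_raw(self, X) -> np.ndarray:
        """De-standardized quaternion components before renormalization."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        Xs = apply_standardization(self.stats_, X=X)
        out = self.model_(Tensor(Xs)).data
        return invert_standardization(self.stats_, Ys=out)

    def predict(self, X) -> np.ndarray:
        """Unit quaternions, shape (N, m, 15, 4)."""
        raw = self.predict_raw(X)
        q = raw.reshape(raw.shape[0], raw.shape[1], len(SEGMENT_NAMES), 4)
        n = np.linalg.norm(q, axis=-1, keepdims=True)
        return q / np.maximum(n, 1e-12)

    def mae(self, X, Y) -> float:
        """Mean absolute error on raw quaternion components."""
        return float(np.mean(np.abs(self.predict_raw(X) - np.asarray(Y))))

    def save(self, path):
        """Single-file checkpoint: versioned header + parameter arrays."""
        check_is_fitted(self, "model_")
        import json

        header = {
            "format": "rehabkit-motion-checkpoint",
            "version": 1,
            "params": self.get_params(),
            "stats": {
                k: getattr(self.stats_, k).tolist()
                for k in ("x_mean", "x_std", "y_mean", "y_std")
            },
        }
        arrays = {f"p{i}": a for i, a in enumerate(self.model_.state_arrays())}
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "MotionInferenceRegressor":
        import json

        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            if header.get("format") != "rehabkit-motion-checkpoint":
                raise ValueError(f"{path}: not a rehabkit motion checkpoint")
            est = cls(**header["params"])
            est.stats_ = StandardizationStats(
                **{k: np.array(v) for k, v in header["stats"].items()}
            )
            cfg = est._config()
            rng = np.random.default_rng(0)  # shapes only; weights overwritten
            est.model_ = _ARCH_CLASSES[cfg.architecture](rng, cfg)
            n = len(est.model_.parameters())
            est.model_.load_state_arrays([data[f"p{i}"] for i in range(n)])
        est.n_features_in_ = _N_IN
        return est


def train_model(X, Y, cfg: ModelConfig = ModelConfig(), seed=None, tol=None):
    """Functional wrapper: fit a :class:`MotionInferenceRegressor`."""
    est = MotionInferenceRegressor(
        architecture=cfg.architecture, epochs=cfg.epochs, lr=cfg.lr,
        batch_size=cfg.batch_size, hidden_size=cfg.hidden_size,
        dropout=cfg.dropout, tol=tol, random_state=seed,
    )
    est.fit(X, Y)
    return est, est.loss_history_


def predict_upper_body(model: MotionInferenceRegressor, X) -> np.ndarray:
    """Functional wrapper over :meth:`MotionInferenceRegressor.predict`."""
    return model.predict(X)
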