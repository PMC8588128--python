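"""Shallow temporal/spatial convolutional network for motor-imagery EEG.

Layer order: temporal convolution (45x1 kernel, 40 filters, stride 2,
downsampling 250 -> 125 Hz) -> spatial convolution (1 x n_channels, 40
filters) -> batch normalization -> squaring nonlinearity -> average
pooling (45, stride 1) -> max pooling (window 8, stride 8) -> log
activation -> dropout -> dense softmax.  The square / average-pool / log
head computes log windowed band power, the neural analogue of the
log-variance features used by filter-bank CSP.

The network, its backward pass, the Adam optimizer, max-norm weight
constraints and early stopping are implemented directly on NumPy arrays.
Training is cropped: each sliding window inherits its trial's label.

For the 22-channel, 4-class, 1000-sample configuration the architecture
has 45,804 trainable weights (temporal 45*40+40, spatial 22*40*40+40,
batch-norm 80, dense 2160*4+4); the 3-channel, 2-class variant has
11,082.  Both counts are asserted in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SCNN",
    "build_model",
    "count_parameters",
    "train",
    "predict_deterministic",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    n_channels: int = 22
    n_classes: int = 4
    input_samples: int = 1000
    temporal_filter_len: int = 45
    temporal_stride: int = 2
    n_temporal_filters: int = 40
    n_spatial_filters: int = 40
    avgpool_len: int = 45
    maxpool_window: int = 8
    maxpool_stride: int = 8
    dropout_rate: float = 0.5
    maxnorm_conv: float = 2.0
    maxnorm_dense: float = 0.5
    log_epsilon: float = 1e-6
    bn_momentum: float = 0.99
    bn_epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2 or self.n_channels < 1:
            raise ValueError("need n_classes >= 2 and n_channels >= 1")
        for name, v in self.shape_chain().items():
            if v < 1:
                raise ValueError(f"input too short for the pooling chain ({name}={v})")

    def shape_chain(self) -> dict[str, int]:
        """Temporal sizes through the network for `input_samples`-long input."""
        t1 = (self.input_samples - self.temporal_filter_len) // self.temporal_stride + 1
        t2 = t1 - self.avgpool_len + 1
        t3 = (t2 - self.maxpool_window) // self.maxpool_stride + 1
        return {"conv_out": t1, "avgpool_out": t2, "maxpool_out": t3}

    @property
    def n_features(self) -> int:
        """Flattened dimensionality entering the dense softmax layer."""
        return self.shape_chain()["maxpool_out"] * self.n_spatial_filters


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_patience: int = 10
    es_patience: int = 20
    max_epochs: int = 100
    batch_size: int = 64
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.es_patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# model


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class SCNN:
    """Shallow ConvNet with explicit NumPy forward/backward passes.

    Parameters live in ``self.params`` (a name -> array dict); batch-norm
    running statistics in ``self.running_mean`` / ``self.running_var`` are
    not trainable and are excluded from :func:`count_parameters`.
    """

    PARAM_NAMES = ("W_t", "b_t", "W_s", "b_s", "gamma", "beta", "W_d", "b_d")

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        L, Ft, Fs = cfg.temporal_filter_len, cfg.n_temporal_filters, cfg.n_spatial_filters
        ch, C, F = cfg.n_channels, cfg.n_classes, cfg.n_features
        self.params: dict[str, np.ndarray] = {
            "W_t": _glorot(rng, (Ft, L), L, Ft),
            "b_t": np.zeros(Ft),
            "W_s": _glorot(rng, (Fs, Ft, ch), Ft * ch, Fs),
            "b_s": np.zeros(Fs),
            "gamma": np.ones(Fs),
            "beta": np.zeros(Fs),
            "W_d": _glorot(rng, (F, C), F, C),
            "b_d": np.zeros(C),
        }
        self.running_mean = np.zeros(Fs)
        self.running_var = np.ones(Fs)
        self.history: dict[str, list[float]] = {}

    # -- forward -----------------------------------------------------------

    def _conv_stack(self, x: np.ndarray, training: bool):
        """Everything up to (and including) the pre-dropout flatten.

        x : (batch, n_channels, input_samples).  Returns (flat, cache);
        the cache is None outside training mode.
        """
        cfg, p = self.cfg, self.params
        if x.ndim != 3 or x.shape[1] != cfg.n_channels or x.shape[2] != cfg.input_samples:
            raise ValueError(
                f"expected input (batch, {cfg.n_channels}, {cfg.input_samples}), got {x.shape}"
            )
        B = x.shape[0]
        # temporal convolution, channels-last layout (B, T1, ch, L)
        V = sliding_window_view(x, cfg.temporal_filter_len, axis=2)
        V = np.ascontiguousarray(V[:, :, :: cfg.temporal_stride, :].transpose(0, 2, 1, 3))
        h1 = V @ p["W_t"].T + p["b_t"]  # (B, T1, ch, Ft)
        T1 = h1.shape[1]
        # spatial convolution collapses (ch, Ft)
        Wsr = p["W_s"].transpose(2, 1, 0).reshape(-1, cfg.n_spatial_filters)  # (ch*Ft, Fs)
        h1r = h1.reshape(B, T1, -1)
        h2 = h1r @ Wsr + p["b_s"]  # (B, T1, Fs)
        # batch normalization per spatial filter
        if training:
            mean = h2.mean(axis=(0, 1))
            var = h2.var(axis=(0, 1))
            m = cfg.bn_momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + cfg.bn_epsilon)
        h2hat = (h2 - mean) * invstd
        h3 = p["gamma"] * h2hat + p["beta"]
        h4 = h3 * h3
        # average pooling (length A, stride 1) via cumulative sums
        A = cfg.avgpool_len
        c = np.concatenate([np.zeros_like(h4[:, :1]), np.cumsum(h4, axis=1)], axis=1)
        h5 = (c[:, A:] - c[:, :-A]) / A  # (B, T2, Fs)
        # max pooling (window w, stride s)
        w, s = cfg.maxpool_window, cfg.maxpool_stride
        h5win = sliding_window_view(h5, w, axis=1)[:, ::s]  # (B, T3, Fs, w)
        mp_idx = h5win.argmax(axis=-1)
        h6 = np.take_along_axis(h5win, mp_idx[..., None], axis=-1)[..., 0]  # (B, T3, Fs)
        h7 = np.log(h6 + cfg.log_epsilon)
        flat = h7.reshape(B, -1)
        cache = (V, h1r, h2hat, invstd, h3, h5, mp_idx, h6) if training else None
        return flat, cache

    def _dense(self, flat: np.ndarray, mask: np.ndarray | None):
        """Dropout (inverted scaling) + dense + softmax."""
        p_drop = self.cfg.dropout_rate
        h = flat if mask is None else flat * mask / (1.0 - p_drop)
        logits = h @ self.params["W_d"] + self.params["b_d"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True), h

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        dropout_mask: np.ndarray | None = None,
    ) -> np.ndarray:
        """Class-probability rows for a batch of crops."""
        flat, _ = self._conv_stack(x, training=training)
        probs, _ = self._dense(flat, dropout_mask)
        return probs

    def features(self, x: np.ndarray) -> np.ndarray:
        """Deterministic activations entering the first dropout layer.

        This is the sub-network output that Monte Carlo dropout caches
        once and reuses across the T stochastic passes.
        """
        flat, _ = self._conv_stack(x, training=False)
        return flat

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, x, y_onehot, dropout_mask):
        """Cross-entropy loss and gradients for one training batch."""
        cfg, p = self.cfg, self.params
        B = x.shape[0]
        flat, cache = self._conv_stack(x, training=True)
        probs, h_drop = self._dense(flat, dropout_mask)
        V, h1r, h2hat, invstd, h3, h5, mp_idx, h6 = cache
        loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))

        g: dict[str, np.ndarray] = {}
        dlogits = (probs - y_onehot) / B
        g["W_d"] = h_drop.T @ dlogits
        g["b_d"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["W_d"].T
        if dropout_mask is not None:
            dflat = dflat * dropout_mask / (1.0 - cfg.dropout_rate)
        T3 = cfg.shape_chain()["maxpool_out"]
        Fs = cfg.n_spatial_filters
        dh7 = dflat.reshape(B, T3, Fs)
        dh6 = dh7 / (h6 + cfg.log_epsilon)
        # max-pool scatter
        w, s = cfg.maxpool_window, cfg.maxpool_stride
        dh5w = np.zeros((B, T3, Fs, w))
        np.put_along_axis(dh5w, mp_idx[..., None], dh6[..., None], axis=-1)
        dh5 = np.zeros_like(h5)
        if s == w:
            dh5[:, : T3 * s] = dh5w.transpose(0, 1, 3, 2).reshape(B, T3 * s, Fs)
        else:  # overlapping or gapped windows
            for t in range(T3):
                dh5[:, t * s : t * s + w] += dh5w[:, t].transpose(0, 2, 1)
        # average-pool transpose: each input sample feeds the windows covering it
        A = cfg.avgpool_len
        T2 = h5.shape[1]
        c = np.concatenate([np.zeros_like(dh5[:, :1]), np.cumsum(dh5, axis=1)], axis=1)
        t_in = np.arange(T2 + A - 1)
        hi = np.minimum(t_in, T2 - 1) + 1
        lo = np.maximum(t_in - (A - 1), 0)
        dh4 = (c[:, hi] - c[:, lo]) / A
        dh3 = 2.0 * h3 * dh4
        # batch-norm backward (batch statistics over B*T1)
        g["gamma"] = np.sum(dh3 * h2hat, axis=(0, 1))
        g["beta"] = np.sum(dh3, axis=(0, 1))
        N = dh3.shape[0] * dh3.shape[1]
        dh2 = (p["gamma"] * invstd / N) * (
            N * dh3 - g["beta"] - h2hat * g["gamma"]
        )
        Wsr = p["W_s"].transpose(2, 1, 0).reshape(-1, Fs)
        T1 = h1r.shape[1]
        dh2f = dh2.reshape(B * T1, Fs)
        g["W_s"] = (
            (h1r.reshape(B * T1, -1).T @ dh2f)
            .reshape(cfg.n_channels, cfg.n_temporal_filters, Fs)
            .transpose(2, 1, 0)
        )
        g["b_s"] = dh2f.sum(axis=0)
        dh1 = (dh2f @ Wsr.T).reshape(B, T1, cfg.n_channels, cfg.n_temporal_filters)
        g["W_t"] = dh1.reshape(-1, cfg.n_temporal_filters).T @ V.reshape(
            -1, cfg.temporal_filter_len
        )
        g["b_t"] = dh1.sum(axis=(0, 1, 2))
        return loss, g

    # -- constraints -------------------------------------------------------

    def apply_maxnorm(self) -> None:
        """Rescale weights whose norms exceed the max-norm constants.

        Convolution kernels are constrained per output filter; the dense
        kernel per class (its incoming-weight vector).
        """
        cfg, p = self.cfg, self.params

        def clip(W, c, axes):
            n = np.sqrt(np.sum(W * W, axis=axes, keepdims=True))
            W *= np.minimum(1.0, c / np.maximum(n, 1e-12))

        clip(p["W_t"], cfg.maxnorm_conv, (1,))
        clip(p["W_s"], cfg.maxnorm_conv, (1, 2))
        clip(p["W_d"], cfg.maxnorm_dense, (0,))

    def kernel_norms(self) -> dict[str, float]:
        p = self.params
        return {
            "temporal": float(np.linalg.norm(p["W_t"], axis=1).max()),
            "spatial": float(np.sqrt((p["W_s"] ** 2).sum(axis=(1, 2))).max()),
            "dense": float(np.linalg.norm(p["W_d"], axis=0).max()),
        }

    def copy_params(self):
        return {k: v.copy() for k, v in self.params.items()}


def build_model(cfg: ModelConfig, seed: int = 0) -> SCNN:
    """Instantiate an untrained network for ``cfg``."""
    return SCNN(cfg, seed=seed)


def count_parameters(m: SCNN) -> int:
    """Trainable weights, including batch-norm scale/shift, excluding
    its running statistics."""
    return int(sum(v.size for v in m.params.values()))


def predict_deterministic(m: SCNN, inputs: np.ndarray) -> np.ndarray:
    """Probability rows with dropout inactive (standard inference)."""
    return m.forward(np.asarray(inputs, dtype=np.float64), training=False)


# ---------------------------------------------------------------------------
# training


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _eval_loss(m: SCNN, x: np.ndarray, y: np.ndarray, batch: int = 256):
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        probs = m.forward(x[i : i + batch], training=False)
        yy = y[i : i + batch]
        losses.append(-np.mean(np.log(probs[np.arange(len(yy)), yy] + 1e-12)) * len(yy))
        correct += int((probs.argmax(axis=1) == yy).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(m: SCNN, crops, val, tc: TrainConfig) -> SCNN:
    """Fit with Adam, max-norm constraints, LR-plateau decay and early
    stopping on validation loss; restores the best weights on exit.

    ``crops`` and ``val`` are :class:`~bciuq.preprocessing.CropBatch`
    instances (or any objects with ``crops`` and ``label`` arrays).
    """
    x, y = np.asarray(crops.crops, dtype=np.float64), np.asarray(crops.label)
    xv, yv = np.asarray(val.crops, dtype=np.float64), np.asarray(val.label)
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels cover a single class")
    C, F = m.cfg.n_classes, m.cfg.n_features
    rng = np.random.default_rng(tc.seed)
    yoh = _onehot(y, C)
    state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in m.params.items()}
    lr = tc.learning_rate
    step = 0
    best_loss, best_params, best_epoch = np.inf, m.copy_params(), 0
    lr_wait = 0
    hist: dict[str, list[float]] = {"loss": [], "val_loss": [], "val_acc": [], "lr": []}

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(x))
        epoch_losses = []
        for i in range(0, len(order), tc.batch_size):
            idx = order[i : i + tc.batch_size]
            mask = None
            if m.cfg.dropout_rate > 0:
                mask = (rng.random((len(idx), F)) >= m.cfg.dropout_rate).astype(float)
            loss, grads = m.loss_and_grads(x[idx], yoh[idx], mask)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            epoch_losses.append(loss)
            step += 1
            b1, b2 = tc.adam_beta1, tc.adam_beta2
            for k, gk in grads.items():
                mom, vel = state[k]
                mom *= b1
                mom += (1 - b1) * gk
                vel *= b2
                vel += (1 - b2) * gk * gk
                mhat = mom / (1 - b1**step)
                vhat = vel / (1 - b2**step)
                m.params[k] -= lr * mhat / (np.sqrt(vhat) + tc.adam_eps)
            m.apply_maxnorm()

        val_loss, val_acc = _eval_loss(m, xv, yv)
        hist["loss"].append(float(np.mean(epoch_losses)))
        hist["val_loss"].append(val_loss)
        hist["val_acc"].append(val_acc)
        hist["lr"].append(lr)
        if val_loss < best_loss - 1e-12:
            best_loss, best_params, best_epoch = val_loss, m.copy_params(), epoch
            lr_wait = 0
        else:
            lr_wait += 1
            if lr_wait >= tc.lr_patience:
                lr *= tc.lr_decay_factor
                lr_wait = 0
        if epoch - best_epoch >= tc.es_patience:
            break

    m.params = best_params
    m.history = hist
    return m


# ---------------------------------------------------------------------------
# serialization


def save_model(m: SCNN, path: str) -> None:
    """Checkpoint parameters + running stats + config to one ``.npz``."""
    np.savez(
        path,
        config=json.dumps(asdict(m.cfg)),
        running_mean=m.running_mean,
        running_var=m.running_var,
        **m.params,
    )


def load_model(path: str) -> SCNN:
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig(**json.loads(str(z["config"])))
        m = SCNN(cfg)
        for k in m.params:
            m.params[k] = z[k]
        m.running_mean = z["running_mean"]
        m.running_var = z["running_var"]
    return m
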