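"""Monte Carlo dropout inference, single-model and ensemble.

Dropout stays active at test time; T stochastic forward passes yield the
predictive distribution {p_t} whose mean p* is the MCD prediction.
Because the only dropout layer sits directly before the dense softmax,
the convolutional sub-network is evaluated once and its activations are
cached and reused across the T passes — bit-identical to running T full
passes with the same mask stream, at a fraction of the cost.

Mask stream: one seeded generator, masks drawn in (pass, member, crop)
order, independent across all three axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scnn import SCNN

__all__ = [
    "PredictiveDistribution",
    "mcd_predict",
    "mcd_predict_naive",
    "trial_predict",
    "ensemble_predict",
]

DEFAULT_T = 50


@dataclass
class PredictiveDistribution:
    """T per-pass class-probability rows and their average p*."""

    P: np.ndarray  # (T, C)
    p_star: np.ndarray  # (C,)
    T: int
    source: str = "single-model"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 2 or self.P.shape[0] != self.T:
            raise ValueError("P must be (T, C)")
        if np.any(self.P < -1e-9) or np.any(np.abs(self.P.sum(axis=1) - 1) > 1e-6):
            raise ValueError("P rows must lie on the probability simplex")
        if np.max(np.abs(self.p_star - self.P.mean(axis=0))) > 1e-12:
            raise ValueError("p_star must equal the column mean of P")

    @property
    def n_classes(self) -> int:
        return self.P.shape[1]

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.p_star))


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x[None] if x.ndim == 2 else x


def _passes(models: list[SCNN], x: np.ndarray, T: int, seed) -> np.ndarray:
    """(T, C) matrix: per pass, softmax averaged over models then crops."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if len(x) == 0:
        raise ValueError("empty crop set")
    dims = {(m.cfg.n_classes, m.cfg.n_channels, m.cfg.input_samples) for m in models}
    if len(dims) != 1:
        raise ValueError("ensemble members must share input/output dimensions")
    rng = np.random.default_rng(seed)
    feats = [m.features(x) for m in models]
    C = models[0].cfg.n_classes
    P = np.empty((T, C))
    for t in range(T):
        acc = np.zeros((len(x), C))
        for m, f in zip(models, feats):
            mask = None
            if m.cfg.dropout_rate > 0:
                mask = (rng.random(f.shape) >= m.cfg.dropout_rate).astype(float)
            probs, _ = m._dense(f, mask)
            acc += probs
        P[t] = (acc / len(models)).mean(axis=0)
    return P


def mcd_predict(m: SCNN, x: np.ndarray, T: int = DEFAULT_T, seed=0) -> PredictiveDistribution:
    """Predictive distribution for one input under T fresh dropout masks.

    Uses the cached-activation fast path (conv stack run once)."""
    xb = _as_batch(x)
    if xb.shape[0] != 1:
        raise ValueError("mcd_predict takes a single input; use trial_predict for crops")
    P = _passes([m], xb, T, seed)
    return PredictiveDistribution(P, P.mean(axis=0), T, "single-model")


def mcd_predict_naive(m: SCNN, x: np.ndarray, T: int = DEFAULT_T, seed=0) -> PredictiveDistribution:
    """Reference path running the full network once per pass.

    Consumes the identical mask stream as :func:`mcd_predict`; results
    agree with the fast path to floating-point identity.  Kept for
    verification — it is T times more expensive.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    xb = _as_batch(x)
    rng = np.random.default_rng(seed)
    C = m.cfg.n_classes
    P = np.empty((T, C))
    for t in range(T):
        mask = None
        if m.cfg.dropout_rate > 0:
            mask = (rng.random((xb.shape[0], m.cfg.n_features)) >= m.cfg.dropout_rate).astype(float)
        probs = m.forward(xb, training=False, dropout_mask=mask)
        P[t] = probs.mean(axis=0)
    return PredictiveDistribution(P, P.mean(axis=0), T, "single-model")


def trial_predict(m: SCNN, crops: np.ndarray, T: int = DEFAULT_T, seed=0) -> PredictiveDistribution:
    """Trial-level prediction: per pass, mean softmax over the trial's crops."""
    P = _passes([m], _as_batch(crops), T, seed)
    return PredictiveDistribution(P, P.mean(axis=0), T, "single-model")


def ensemble_predict(
    models: list[SCNN], x: np.ndarray, T: int = DEFAULT_T, seed=0
) -> PredictiveDistribution:
    """MCD of a deep ensemble: per pass, average the members' stochastic
    softmax outputs (independent masks per member), then over crops."""
    if len(models) < 1:
        raise ValueError("need at least one model")
    P = _passes(models, _as_batch(x), T, seed)
    return PredictiveDistribution(P, P.mean(axis=0), T, f"ensemble({len(models)})")
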