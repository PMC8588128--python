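"""Band-pass filtering, exponential moving standardization, crop augmentation.

The standardization is the electrode-wise exponential moving scheme with
decay 0.999: per channel and sample,

    mu(t_i)     = 0.001 x(t_i) + 0.999 mu(t_{i-1})
    sigma2(t_i) = 0.001 (x(t_i) - mu(t_i))^2 + 0.999 sigma2(t_{i-1})
    x~(t_i)     = (x(t_i) - mu(t_i)) / sigma(t_i)

with mu(t_0), sigma2(t_0) initialised from the pre-trial rest baseline and
amplitudes clipped to a +/- 6 sigma band around the running mean to
rectify outliers.  By default clipping uses the previous sample's
statistics (so the recurrences see the clipped value, keeping the update
explicit and causal); ``clip_mode="post_update"`` instead clips against
the statistics updated from the raw sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import TrialSet

__all__ = [
    "StandardizedTrial",
    "CropBatch",
    "bandpass_filter",
    "moving_standardize",
    "standardize_trialset",
    "extract_crops",
    "crops_from_trialset",
]

DEFAULT_DECAY = 0.999
CLIP_SIGMAS = 6.0


@dataclass
class StandardizedTrial:
    """Standardized signal with its running-statistics traces.

    x_tilde, mu_trace, var_trace : (n_channels, n_samples) arrays.
    """

    x_tilde: np.ndarray
    mu_trace: np.ndarray
    var_trace: np.ndarray
    decay: float


@dataclass
class CropBatch:
    """Fixed-length training windows slid across standardized trials."""

    crops: np.ndarray  # (n_crops, n_channels, crop_samples)
    trial_index: np.ndarray  # (n_crops,)
    label: np.ndarray  # (n_crops,)
    sampling_rate: float = 250.0

    def __len__(self) -> int:
        return self.crops.shape[0]

    def for_trial(self, i: int) -> "CropBatch":
        m = self.trial_index == i
        return CropBatch(self.crops[m], self.trial_index[m], self.label[m], self.sampling_rate)


def bandpass_filter(
    ts: TrialSet, low_hz: float = 4.0, high_hz: float = 38.0, order: int = 3
) -> TrialSet:
    """Zero-phase Butterworth band-pass of every channel, trials and rest alike."""
    nyq = ts.sampling_rate / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=ts.sampling_rate, output="sos")
    return TrialSet(
        signals=sps.sosfiltfilt(sos, ts.signals, axis=-1),
        labels=ts.labels,
        sampling_rate=ts.sampling_rate,
        rest=sps.sosfiltfilt(sos, ts.rest, axis=-1),
        subject_id=ts.subject_id,
        channel_names=list(ts.channel_names),
    )


def moving_standardize(
    trial: np.ndarray,
    rest: np.ndarray,
    decay: float = DEFAULT_DECAY,
    clip_mode: str = "pre_update",
) -> StandardizedTrial:
    """Exponential moving standardization of one (channels x samples) trial.

    mu(t0)/sigma2(t0) come from the rest baseline; each sample is clipped
    to the running +/- 6 sigma band before it is standardized.
    """
    if not 0 < decay < 1:
        raise ValueError("decay must lie in (0, 1)")
    trial = np.asarray(trial, dtype=np.float64)
    rest = np.asarray(rest, dtype=np.float64)
    if rest.ndim != 2 or rest.shape[1] < 1:
        raise ValueError("rest baseline must be non-empty per channel")
    if clip_mode not in ("pre_update", "post_update"):
        raise ValueError("clip_mode must be 'pre_update' or 'post_update'")
    n_ch, n_s = trial.shape
    mu = rest.mean(axis=1)
    var = rest.var(axis=1)
    if np.any(var <= 0):
        raise ValueError("degenerate rest baseline: zero variance on a channel")
    alpha = 1.0 - decay
    x_tilde = np.empty_like(trial)
    mu_trace = np.empty_like(trial)
    var_trace = np.empty_like(trial)
    for i in range(n_s):
        x = trial[:, i]
        if clip_mode == "pre_update":
            band = CLIP_SIGMAS * np.sqrt(var)
            x = np.clip(x, mu - band, mu + band)
            mu = alpha * x + decay * mu
            var = alpha * (x - mu) ** 2 + decay * var
        else:
            mu = alpha * x + decay * mu
            var = alpha * (x - mu) ** 2 + decay * var
            band = CLIP_SIGMAS * np.sqrt(var)
            x = np.clip(x, mu - band, mu + band)
        x_tilde[:, i] = (x - mu) / np.sqrt(var)
        mu_trace[:, i] = mu
        var_trace[:, i] = var
    return StandardizedTrial(x_tilde, mu_trace, var_trace, decay)


def standardize_trialset(
    ts: TrialSet, decay: float = DEFAULT_DECAY, clip_mode: str = "pre_update"
) -> TrialSet:
    """Standardize every trial of a TrialSet (rest replaced by its own z-score)."""
    out = np.empty_like(ts.signals)
    rest_out = np.empty_like(ts.rest)
    for i in range(ts.n_trials):
        out[i] = moving_standardize(ts.signals[i], ts.rest[i], decay, clip_mode).x_tilde
        m = ts.rest[i].mean(axis=1, keepdims=True)
        s = ts.rest[i].std(axis=1, keepdims=True)
        rest_out[i] = (ts.rest[i] - m) / np.where(s > 0, s, 1.0)
    return TrialSet(out, ts.labels, ts.sampling_rate, rest_out, ts.subject_id, list(ts.channel_names))


def n_crops_expected(window_samples: int, crop_samples: int, stride_samples: int) -> int:
    return (window_samples - crop_samples) // stride_samples + 1


def extract_crops(
    trial: np.ndarray,
    label: int,
    sampling_rate: float = 250.0,
    crop_seconds: float = 4.0,
    stride_ms: float = 8.0,
    window_s: tuple[float, float] = (-0.5, 4.0),
    cue_offset_s: float = 0.5,
    trial_index: int = 0,
) -> CropBatch:
    """Slide fixed-length crops across one trial.

    ``window_s`` is relative to the cue; ``cue_offset_s`` states how much
    pre-cue signal the trial array starts with.  Crops start every stride
    from the window start; their count is
    floor((window_samples - crop_samples) / stride_samples) + 1 and each
    crop inherits the trial label.
    """
    trial = np.asarray(trial, dtype=np.float64)
    fs = sampling_rate
    crop_n = round(crop_seconds * fs)
    stride_n = max(1, round(stride_ms * fs / 1000.0))
    start = round((cue_offset_s + window_s[0]) * fs)
    stop = round((cue_offset_s + window_s[1]) * fs)
    if start < 0 or stop > trial.shape[1]:
        raise ValueError("requested window exceeds the trial extent")
    win_n = stop - start
    if win_n < crop_n:
        raise ValueError("window shorter than crop length")
    n_crops = n_crops_expected(win_n, crop_n, stride_n)
    starts = start + stride_n * np.arange(n_crops)
    crops = np.stack([trial[:, s : s + crop_n] for s in starts])
    return CropBatch(
        crops=crops,
        trial_index=np.full(n_crops, trial_index, dtype=np.int64),
        label=np.full(n_crops, label, dtype=np.int64),
        sampling_rate=fs,
    )


def crops_from_trialset(
    ts: TrialSet,
    crop_seconds: float = 4.0,
    stride_ms: float = 8.0,
    window_s: tuple[float, float] = (-0.5, 4.0),
    cue_offset_s: float = 0.5,
) -> CropBatch:
    """Concatenate per-trial crops over a whole TrialSet."""
    batches = [
        extract_crops(
            ts.signals[i],
            int(ts.labels[i]),
            ts.sampling_rate,
            crop_seconds,
            stride_ms,
            window_s,
            cue_offset_s,
            trial_index=i,
        )
        for i in range(ts.n_trials)
    ]
    if not batches:
        raise ValueError("empty TrialSet")
    return CropBatch(
        crops=np.concatenate([b.crops for b in batches]),
        trial_index=np.concatenate([b.trial_index for b in batches]),
        label=np.concatenate([b.label for b in batches]),
        sampling_rate=ts.sampling_rate,
    )
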