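"""Synthetic motor-imagery EEG with ERD/ERS structure.

Generates labeled multichannel trials in which imagined hand movement
attenuates the amplitude of the mu (8-12 Hz) and beta (13-30 Hz) rhythms
on configurable channels (event-related desynchronization), on top of
broadband Gaussian background noise.  Each trial carries a pre-cue rest
baseline with unattenuated oscillations, which seeds the exponential
moving standardization downstream.

The signal model is deliberately simple: per trial, each channel is a sum
of two amplitude-scaled sinusoids (mu centred at 10 Hz, beta at 22 Hz,
small per-trial frequency jitter within the band, random phase) plus white
noise.  Band-power statistics of this model are analytically checkable:
a sinusoid of amplitude A carries band power A^2/2, so a configured
attenuation factor a is recoverable as sqrt(P_MI / P_rest) ~ a.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "TrialSet",
    "SimulationConfig",
    "generate_trials",
    "train_test_split_sessions",
    "save_trialset",
    "load_trialset",
    "read_gdf",
]


@dataclass
class TrialSet:
    """Labeled multichannel EEG epochs plus per-trial rest baselines.

    signals : (n_trials, n_channels, n_samples) array, microvolt scale
    labels : (n_trials,) int array with values in {0..C-1}
    rest : (n_trials, n_channels, n_rest_samples) pre-cue baseline
    subject_id : (n_trials,) int array
    """

    signals: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    rest: np.ndarray
    subject_id: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.rest = np.asarray(self.rest, dtype=np.float64)
        self.subject_id = np.asarray(self.subject_id, dtype=np.int64)
        if self.signals.ndim != 3 or self.rest.ndim != 3:
            raise ValueError("signals and rest must be 3-D (trials, channels, samples)")
        n = self.n_trials
        if not (len(self.labels) == n == len(self.subject_id) == self.rest.shape[0]):
            raise ValueError("trial-count mismatch across fields")
        if self.signals.shape[1] != self.rest.shape[1]:
            raise ValueError("channel-count mismatch between signals and rest")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if n and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.n_trials else 0

    def subset(self, idx: np.ndarray) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(
            self.signals[idx],
            self.labels[idx],
            self.sampling_rate,
            self.rest[idx],
            self.subject_id[idx],
            list(self.channel_names),
        )


def _default_class_effect() -> np.ndarray:
    # 2 classes x 3 channels (C3-like, Cz-like, C4-like):
    # class 0 = imagined left hand -> ERD on contralateral C4 (channel 2),
    # class 1 = imagined right hand -> ERD on C3 (channel 0).
    return np.array([[1.0, 1.0, 0.5], [0.5, 1.0, 1.0]])


@dataclass
class SimulationConfig:
    """Conditions for the ERD/ERS simulation.

    class_effect : (n_classes, n_channels) attenuation factors in [0, 1]
        applied to mu/beta amplitude during the MI window (1 = no ERD).
    trial_seconds : duration of the MI window after the cue; the emitted
        signal additionally contains ``pre_cue_seconds`` before the cue so
        that crop windows starting at -0.5 s exist.
    rest_seconds : length of the separate pre-trial rest baseline used to
        initialise the moving-standardization statistics.
    """

    n_trials: int = 50
    n_channels: int = 3
    trial_seconds: float = 4.0
    pre_cue_seconds: float = 0.5
    rest_seconds: float = 2.0
    sampling_rate: float = 250.0
    class_effect: np.ndarray = field(default_factory=_default_class_effect)
    mu_amplitude: float = 10.0
    beta_amplitude: float = 5.0
    noise_sd: float = 3.0
    mu_band: tuple[float, float] = (9.0, 11.0)
    beta_band: tuple[float, float] = (20.0, 24.0)
    seed: int = 0

    def validate(self) -> None:
        ce = np.asarray(self.class_effect, dtype=float)
        if ce.ndim != 2 or ce.shape[1] != self.n_channels:
            raise ValueError("class_effect must be (n_classes, n_channels)")
        if ce.shape[0] < 2:
            raise ValueError("need at least 2 classes")
        if np.any(ce < 0) or np.any(ce > 1):
            raise ValueError("attenuation factors must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if min(self.trial_seconds, self.rest_seconds, self.sampling_rate) <= 0:
            raise ValueError("durations and sampling_rate must be positive")
        if self.pre_cue_seconds < 0:
            raise ValueError("pre_cue_seconds must be non-negative")

    @property
    def n_classes(self) -> int:
        return np.asarray(self.class_effect).shape[0]


def _channel_names(n: int) -> list[str]:
    base = ["C3", "Cz", "C4"]
    if n <= 3:
        return base[:n]
    return base + [f"EEG{i}" for i in range(3, n)]


def generate_trials(config: SimulationConfig) -> TrialSet:
    """Simulate a balanced :class:`TrialSet` under ``config``.

    The rest baseline and the pre-cue part of the signal carry the
    unattenuated rhythms; during the MI window (after the cue) the mu and
    beta amplitudes on each channel are multiplied by the class-specific
    attenuation factor.  Fixed seed implies bit-identical output.
    """
    config.validate()
    fs = config.sampling_rate
    n_mi = round(config.trial_seconds * fs)
    n_pre = round(config.pre_cue_seconds * fs)
    n_sig = n_pre + n_mi
    n_rest = round(config.rest_seconds * fs)
    ce = np.asarray(config.class_effect, dtype=float)
    n_classes, n_ch = ce.shape
    n_total = config.n_trials * n_classes

    rng = np.random.default_rng(config.seed)
    signals = np.empty((n_total, n_ch, n_sig))
    rest = np.empty((n_total, n_ch, n_rest))
    labels = np.repeat(np.arange(n_classes), config.n_trials)

    t_sig = np.arange(n_sig) / fs
    t_rest = np.arange(-n_rest, 0) / fs
    # amplitude envelope: attenuation applies only after the cue
    gate = np.ones(n_sig)
    for i, lab in enumerate(labels):
        for ch in range(n_ch):
            att = ce[lab, ch]
            env = gate.copy()
            env[n_pre:] = att
            signals[i, ch] = 0.0
            rest[i, ch] = 0.0
            for (f_lo, f_hi), amp in (
                (config.mu_band, config.mu_amplitude),
                (config.beta_band, config.beta_amplitude),
            ):
                f = rng.uniform(f_lo, f_hi)
                phi = rng.uniform(0, 2 * np.pi)
                signals[i, ch] += env * amp * np.sin(2 * np.pi * f * t_sig + phi)
                rest[i, ch] += amp * np.sin(2 * np.pi * f * t_rest + phi)
            if config.noise_sd > 0:
                signals[i, ch] += rng.normal(0, config.noise_sd, n_sig)
                rest[i, ch] += rng.normal(0, config.noise_sd, n_rest)

    return TrialSet(
        signals=signals,
        labels=labels,
        sampling_rate=fs,
        rest=rest,
        subject_id=np.zeros(n_total, dtype=np.int64),
        channel_names=_channel_names(n_ch),
    )


def train_test_split_sessions(
    ts: TrialSet, fraction_test: float, seed: int
) -> tuple[TrialSet, TrialSet]:
    """Class-balanced random partition into (train, test).

    Disjoint, union reconstructs the input multiset; per-class counts in
    the two halves differ from exact proportionality by at most one trial.
    """
    if not 0 < fraction_test < 1:
        raise ValueError("fraction_test must lie in (0, 1)")
    classes = np.unique(ts.labels)
    if ts.n_trials < len(classes) or len(classes) < 2:
        raise ValueError("need at least one trial per class and >= 2 classes")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(ts.labels == c)
        idx = rng.permutation(idx)
        n_test = int(round(fraction_test * len(idx)))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return ts.subset(tr), ts.subset(te)


# ---------------------------------------------------------------------------
# persistence


def save_trialset(ts: TrialSet, path: str) -> None:
    """Write a TrialSet to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=ts.signals)
        f.create_dataset("rest", data=ts.rest)
        f.create_dataset("labels", data=ts.labels)
        f.create_dataset("subject_id", data=ts.subject_id)
        f.attrs["sampling_rate"] = ts.sampling_rate
        f.attrs["channel_names"] = [str(c) for c in ts.channel_names]


def load_trialset(path: str) -> TrialSet:
    with h5py.File(path, "r") as f:
        return TrialSet(
            signals=f["signals"][()],
            labels=f["labels"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            rest=f["rest"][()],
            subject_id=f["subject_id"][()],
            channel_names=[str(c) for c in f.attrs["channel_names"]],
        )


def read_gdf(
    path: str,
    event_map: dict[str, int],
    channels: list[str] | None = None,
    tmin: float = -0.5,
    tmax: float = 4.0,
    rest_seconds: float = 2.0,
    subject_id: int = 0,
) -> TrialSet:
    """Adapter reading a BCI Competition IV 2a/2b GDF recording.

    ``event_map`` maps annotation descriptions (e.g. ``"769"`` for left
    hand) to integer class labels.  The rest baseline is taken from the
    ``rest_seconds`` immediately preceding each epoch window.  Requires
    :mod:`mne` (optional extra ``gdf``); provided for completeness and not
    exercised against the competition files in the test suite.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading GDF requires mne (pip install bciuq[gdf])") from e

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    fs = raw.info["sfreq"]
    events, desc_map = mne.events_from_annotations(raw, verbose="error")
    wanted = {code: lab for desc, lab in event_map.items() if (code := desc_map.get(desc))}
    sel = np.isin(events[:, 2], list(wanted))
    events = events[sel]
    data = raw.get_data(units="uV")
    n_pre = round(-tmin * fs)
    n_sig = round((tmax - tmin) * fs)
    n_rest = round(rest_seconds * fs)
    sigs, rests, labels = [], [], []
    for onset, _, code in events:
        start = onset + round(tmin * fs)
        if start - n_rest < 0 or start + n_sig > data.shape[1]:
            continue
        sigs.append(data[:, start : start + n_sig])
        rests.append(data[:, start - n_rest : start])
        labels.append(wanted[code])
    return TrialSet(
        signals=np.array(sigs),
        labels=np.array(labels, dtype=np.int64),
        sampling_rate=fs,
        rest=np.array(rests),
        subject_id=np.full(len(labels), subject_id, dtype=np.int64),
        channel_names=list(raw.ch_names),
    )
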