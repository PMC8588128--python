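import numpy as np
import pytest

from bciuq import (
    ExperimentConfig,
    ModelConfig,
    SimulationConfig,
    TrainConfig,
    bandpass_filter,
    build_model,
    generate_trials,
    standardize_trialset,
    train,
    train_test_split_sessions,
)
from bciuq.experiment import _crop, make_splits

# scaled-down study conditions shared across tests: 3 channels
# (C3/Cz/C4-like), 2 classes, 250 Hz, 2 s MI window, 2 s / 500-sample crops
SMALL_MODEL = dict(n_channels=3, n_classes=2, input_samples=500, dropout_rate=0.5)
SMALL_CROPS = dict(crop_seconds=2.0, crop_stride_ms=500.0, crop_window_s=(-0.5, 2.0))
STRONG_SEP = dict(class_effect=np.array([[1, 1, 0.2], [0.2, 1, 1]]), noise_sd=2.0)
OVERLAP = dict(class_effect=np.array([[1, 1, 0.7], [0.7, 1, 1]]), noise_sd=10.0)


def make_dataset(effect_kw, n_trials=30, seed=0):
    cfg = SimulationConfig(
        n_trials=n_trials,
        trial_seconds=2.0,
        pre_cue_seconds=0.5,
        rest_seconds=1.0,
        seed=seed,
        **effect_kw,
    )
    ts = standardize_trialset(bandpass_filter(generate_trials(cfg)))
    return train_test_split_sessions(ts, 0.3, seed=seed)


def fit_one(train_ts, seed=0, dropout=0.5, max_epochs=40):
    mc = ModelConfig(**{**SMALL_MODEL, "dropout_rate": dropout})
    ecfg = ExperimentConfig(
        n_repeats=1,
        validation_fraction=0.2,
        model=mc,
        training=TrainConfig(
            max_epochs=max_epochs, es_patience=10, lr_patience=5, batch_size=32, seed=seed
        ),
        seed=seed,
        **SMALL_CROPS,
    )
    tr_idx, va_idx = make_splits(train_ts, ecfg)[0]
    m = train(
        build_model(mc, seed=seed),
        _crop(train_ts.subset(tr_idx), ecfg),
        _crop(train_ts.subset(va_idx), ecfg),
        ecfg.training,
    )
    return m, ecfg


@pytest.fixture(scope="session")
def separable_data():
    return make_dataset(STRONG_SEP, seed=0)


@pytest.fixture(scope="session")
def overlap_data():
    return make_dataset(OVERLAP, seed=1)


@pytest.fixture(scope="session")
def trained_model(separable_data):
    """One network fitted on the strongly separable synthetic condition."""
    tr, te = separable_data
    m, ecfg = fit_one(tr, seed=0)
    crops_te = _crop(te, ecfg)
    labels = np.array([te.labels[i] for i in np.unique(crops_te.trial_index)])
    return m, crops_te, labels, ecfg
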