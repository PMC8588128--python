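"""Repeated-holdout experiments: training, MCD/ensemble evaluation, reports.

The experiment design mirrors session-to-session BCI evaluation: a fixed
test set is held out; the training pool is split randomly into
train/validation parts n_repeats times (default 16); one network is
trained per split; the repeat models double as a deep ensemble.  Under
the subject-specific strategy splits are drawn within one subject's
trials, under the non-subject-specific strategy from the pooled trials
of all subjects.

Accuracy is trial-level: a trial's predicted class is argmax of p* from
its crop-averaged predictive distribution (crop-level evaluation is
available via ``trial_level=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import CropBatch, crops_from_trialset
from .scnn import SCNN, ModelConfig, TrainConfig, build_model, predict_deterministic, train
from .synthetic import TrialSet
from .mcd import ensemble_predict, trial_predict
from .uncertainty import compute_measures, decide, evaluate_uncertainty

__all__ = [
    "ExperimentConfig",
    "make_splits",
    "run_experiment",
    "coadaptation_check",
    "evaluate_trials",
]


@dataclass
class ExperimentConfig:
    strategy: str = "subject-specific"  # or "non-subject-specific"
    n_repeats: int = 16
    validation_fraction: float = 1.0 / 6.0
    T_list: tuple[int, ...] = (1, 50)
    alpha: float = 0.05
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    crop_seconds: float = 4.0
    crop_stride_ms: float = 8.0
    crop_window_s: tuple[float, float] = (-0.5, 4.0)
    cue_offset_s: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.strategy not in ("subject-specific", "non-subject-specific"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def make_splits(
    train_set: TrialSet, cfg: ExperimentConfig, subject: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """n_repeats random disjoint (train_idx, val_idx) partitions.

    Subject-specific splits draw only within ``subject``'s trials;
    non-subject-specific splits draw from the pooled training set.
    Seeded: identical config and seed give identical split lists.
    """
    if cfg.strategy == "subject-specific":
        if subject is None:
            subject = int(train_set.subject_id[0])
        pool = np.flatnonzero(train_set.subject_id == subject)
    else:
        pool = np.arange(train_set.n_trials)
    n_val = int(round(cfg.validation_fraction * len(pool)))
    if n_val < 1 or n_val >= len(pool):
        raise ValueError("validation fraction yields an empty train or validation part")
    rng = np.random.default_rng(cfg.seed)
    splits = []
    for _ in range(cfg.n_repeats):
        perm = rng.permutation(pool)
        splits.append((np.sort(perm[n_val:]), np.sort(perm[:n_val])))
    return splits


def _crop(ts: TrialSet, cfg: ExperimentConfig) -> CropBatch:
    return crops_from_trialset(
        ts, cfg.crop_seconds, cfg.crop_stride_ms, cfg.crop_window_s, cfg.cue_offset_s
    )


def evaluate_trials(
    models: SCNN | list[SCNN],
    test_crops: CropBatch,
    labels: np.ndarray,
    T: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Trial-level MCD evaluation on a fixed test set.

    Returns (accuracy, predictive distributions, decisions, report, table)
    where table is the per-trial measure DataFrame.
    """
    single = isinstance(models, SCNN)
    trial_ids = np.unique(test_crops.trial_index)
    pds, decisions, rows = [], [], []
    for k, ti in enumerate(trial_ids):
        crops_i = test_crops.for_trial(int(ti)).crops
        if single:
            pd_ = trial_predict(models, crops_i, T=T, seed=seed + k)
        else:
            pd_ = ensemble_predict(models, crops_i, T=T, seed=seed + k)
        dec = decide(pd_, alpha=alpha)
        meas = compute_measures(pd_)
        pds.append(pd_)
        decisions.append(dec)
        rows.append(
            {
                "trial": int(ti),
                "c": dec.predicted_class,
                "true": int(labels[k]),
                "M": meas.M,
                "sigma_d": meas.sigma_d,
                "M_hat": dec.threshold,
                "certain": dec.certain,
                "VR": meas.VR,
                "H": meas.H,
                "Hn": meas.Hn,
                "I": meas.I,
                "Vtot": meas.Vtot,
            }
        )
    report = evaluate_uncertainty(decisions, labels)
    acc = float(np.mean([d.predicted_class == y for d, y in zip(decisions, labels)]))
    return acc, pds, decisions, report, pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig, train_set: TrialSet, test_set: TrialSet):
    """Train one model per repeated-holdout split and evaluate on the test set.

    Returns (result_table, models, details): the table holds per-repeat
    deterministic accuracy, MCD accuracy for each T in ``cfg.T_list`` with
    its improvement over the T=1 baseline, and the certainty-report
    columns at ``cfg.alpha``; a final ``mean`` row averages the repeats.
    The repeat models are returned for ensemble use.
    """
    splits = make_splits(train_set, cfg)
    test_crops = _crop(test_set, cfg)
    labels = np.array(
        [test_set.labels[i] for i in np.unique(test_crops.trial_index)]
    )
    rng = np.random.default_rng(cfg.seed + 1)
    models: list[SCNN] = []
    rows = []
    details: dict = {"per_trial": {}}
    for r, (tr_idx, va_idx) in enumerate(splits):
        m = build_model(cfg.model, seed=int(rng.integers(2**31)))
        tc = TrainConfig(**{**cfg.training.__dict__, "seed": int(rng.integers(2**31))})
        m = train(m, _crop(train_set.subset(tr_idx), cfg), _crop(train_set.subset(va_idx), cfg), tc)
        models.append(m)
        row: dict = {"repeat": r}
        # deterministic trial-level accuracy
        det_correct = []
        for ti in np.unique(test_crops.trial_index):
            probs = predict_deterministic(m, test_crops.for_trial(int(ti)).crops)
            det_correct.append(probs.mean(axis=0).argmax())
        row["acc_det"] = float(np.mean(np.array(det_correct) == labels))
        for T in cfg.T_list:
            acc, _, _, report, table = evaluate_trials(
                m, test_crops, labels, T=T, seed=cfg.seed + 1000 * r, alpha=cfg.alpha
            )
            row[f"acc_T{T}"] = acc
            if T == max(cfg.T_list):
                row.update(
                    Rc=report.Rc, Rcc=report.Rcc, Riu=report.Riu, UA=report.UA
                )
                details["per_trial"][r] = table
        base = row.get("acc_T1", row["acc_det"])
        for T in cfg.T_list:
            row[f"dacc_T{T}"] = row[f"acc_T{T}"] - base
        rows.append(row)
    result = pd.DataFrame(rows)
    mean_row = result.drop(columns="repeat").mean(numeric_only=True)
    mean_row["repeat"] = "mean"
    result = pd.concat([result, mean_row.to_frame().T], ignore_index=True)

    # ensemble of the repeat models at the largest T
    T_ens = max(cfg.T_list)
    ens_acc, _, _, ens_report, ens_table = evaluate_trials(
        models, test_crops, labels, T=T_ens, seed=cfg.seed + 999, alpha=cfg.alpha
    )
    details["ensemble"] = {
        "acc": ens_acc,
        "Rc": ens_report.Rc,
        "Rcc": ens_report.Rcc,
        "Riu": ens_report.Riu,
        "UA": ens_report.UA,
        "per_trial": ens_table,
    }
    return result, models, details


def coadaptation_check(
    models: list[SCNN], test_crops: CropBatch, labels: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Per-model ACC(T=1, dropout on) - ACC(deterministic) on the test set.

    Negative values indicate co-adaptation: neurons relying on each
    other's presence so that test-time dropout hurts.
    """
    if not models:
        raise ValueError("need at least one model")
    trial_ids = np.unique(test_crops.trial_index)
    out = []
    for k, m in enumerate(models):
        det, mcd1 = [], []
        for j, ti in enumerate(trial_ids):
            crops_i = test_crops.for_trial(int(ti)).crops
            det.append(predict_deterministic(m, crops_i).mean(axis=0).argmax())
            mcd1.append(trial_predict(m, crops_i, T=1, seed=seed + 7919 * k + j).predicted_class)
        acc_det = np.mean(np.array(det) == labels)
        acc_1 = np.mean(np.array(mcd1) == labels)
        out.append(acc_1 - acc_det)
    return np.asarray(out)
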