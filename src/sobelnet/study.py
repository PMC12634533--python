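"""Desk-scale reference study on synthetic EEG.

A compact, fully seeded pipeline exercising every stage end to end on one
CPU: simulate a 16-subject cohort, train, run the chance-level control, the
noise-robustness sweep and the filter-count sweep.  Problem sizes are scaled
for desk hardware: 8 MDD + 8 HC subjects, 60-s recordings sampled at 64 Hz
(all four rhythms remain below Nyquist), non-overlapping 4-s windows, and a
short training schedule — the network reaches ceiling validation accuracy on
strongly separable data within a couple of passes, so long schedules add
nothing here.  The chance-level control segments the held-out subjects with
a denser 0.5-s stride so its accuracy estimate is tight around 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import ModelParams
from .robustness import NoiseCondition, robustness_sweep
from .sobel import build_filter_bank
from .synth import Epoch, dataset_epochs, extract_epochs, generate_dataset
from .training import (TrainConfig, evaluate, filter_count_sweep,
                       subject_split, train)

#: Study conditions (see module docstring).
N_PER_CLASS = (8, 8)
DURATION_S = 60.0
SAMPLING_RATE = 64.0
EFFECT_LARGE = 3.0
WINDOW_S = 4.0
STRIDE_S = 4.0
CONTROL_STRIDE_S = 0.5
NOMINAL_SNRS_DB = (20.0, 15.0, 10.0, 5.0, 0.0, -5.0)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)


def desk_config(seed: int, n_epochs: int = 8, nf: int = 10) -> TrainConfig:
    return TrainConfig(seed=_sub_seed(seed, 1), n_epochs=n_epochs,
                       batch_size=32, nf=nf)


def desk_epochs(seed: int, effect_size: float = EFFECT_LARGE,
                stride_s: float = STRIDE_S) -> list[Epoch]:
    recs = generate_dataset(
        N_PER_CLASS, seed=_sub_seed(seed, 0), duration_s=DURATION_S,
        sampling_rate=SAMPLING_RATE, effect_size=effect_size,
    )
    return dataset_epochs(recs, window_s=WINDOW_S, stride_s=stride_s)


def train_separable(seed: int, n_epochs: int = 8):
    """Train on strongly separable synthetic data.

    Returns (params, curve, epochs, assignment); the final curve row carries
    the validation accuracy the end-to-end recovery check reads.
    """
    eps = desk_epochs(seed)
    cfg = desk_config(seed, n_epochs=n_epochs)
    assignment = subject_split(eps, cfg.split, cfg.seed)
    params, curve = train(eps, cfg, assignment=assignment)
    return params, curve, eps, assignment


def shuffled_label_control(seed: int, n_epochs: int = 4) -> float:
    """Permute epoch labels and retrain; returns final validation accuracy.

    With labels independent of the signal the classifier cannot beat chance
    on held-out subjects, so this should land near 0.5.  Held-out subjects
    are segmented with a dense stride to shrink the binomial error of the
    estimate.
    """
    coarse = desk_epochs(seed)
    cfg = desk_config(seed, n_epochs=n_epochs)
    assignment = subject_split(coarse, cfg.split, cfg.seed)
    recs = generate_dataset(
        N_PER_CLASS, seed=_sub_seed(seed, 0), duration_s=DURATION_S,
        sampling_rate=SAMPLING_RATE, effect_size=EFFECT_LARGE,
    )
    eps: list[Epoch] = []
    for rec in recs:
        stride = STRIDE_S if assignment[rec.subject_id] == "train" else CONTROL_STRIDE_S
        eps.extend(extract_epochs(rec, WINDOW_S, stride))
    rng = np.random.default_rng(_sub_seed(seed, 2))
    labels = np.array([e.label for e in eps])
    rng.shuffle(labels)
    shuffled = [
        Epoch(values=e.values, label=int(l), subject_id=e.subject_id, index=e.index)
        for e, l in zip(eps, labels)
    ]
    _, curve = train(shuffled, cfg, assignment=assignment)
    return float(curve["val_acc"].iloc[-1])


def robustness_study(params: ModelParams, eps: list[Epoch],
                     assignment: dict[str, str], seed: int) -> pd.DataFrame:
    """Noise sweep over the nominal SNR grid on the held-out test subjects."""
    test_eps = [e for e in eps if assignment[e.subject_id] == "test"]
    cond_seeds = np.random.SeedSequence([seed, 3]).generate_state(
        len(NOMINAL_SNRS_DB)) % 2**31
    conditions = [NoiseCondition(target_snr_db=lv, seed=int(s))
                  for lv, s in zip(NOMINAL_SNRS_DB, cond_seeds)]
    bank = build_filter_bank(params.nf)
    return robustness_sweep(params, bank, test_eps, conditions)


def filter_sweep_study(seed: int, nf_values=(10, 20, 30),
                       n_epochs: int = 6) -> pd.DataFrame:
    """Filter-count sensitivity sweep sharing one split and seed."""
    eps = desk_epochs(seed)
    cfg = desk_config(seed, n_epochs=n_epochs)
    return filter_count_sweep(eps, list(nf_values), cfg)


def run_full_study(seed: int) -> dict:
    """Everything the desk study measures, as one flat dict of numbers."""
    params, curve, eps, assignment = train_separable(seed)
    val_acc = float(curve["val_acc"].iloc[-1])
    test_metrics = evaluate(params, [e for e in eps if assignment[e.subject_id] == "test"])
    control_acc = shuffled_label_control(seed)
    report = robustness_study(params, eps, assignment, seed)
    sweep = filter_sweep_study(seed)
    by_snr = report.set_index("nominal_snr_db")
    return {
        "val_accuracy_separable": val_acc,
        "test_accuracy_separable": test_metrics.accuracy,
        "test_sensitivity_separable": test_metrics.sensitivity,
        "test_specificity_separable": test_metrics.specificity,
        "shuffled_label_val_accuracy": control_acc,
        "delta_snr_db_mean": float(report["delta_snr_db"].mean()),
        "delta_snr_db_std_across_conditions": float(report["delta_snr_db"].std(ddof=0)),
        "delta_psnr_db_mean": float(report["delta_psnr_db"].mean()),
        "delta_ssim_mean": float(report["delta_ssim"].mean()),
        "accuracy_at_20db": float(by_snr.loc[20.0, "accuracy"]),
        "accuracy_at_minus5db": float(by_snr.loc[-5.0, "accuracy"]),
        "nf_sweep_accuracy_min": float(sweep["accuracy"].min()),
        "nf_sweep_accuracy_max": float(sweep["accuracy"].max()),
        "nf_sweep_accuracy_spread": float(sweep["accuracy"].max() - sweep["accuracy"].min()),
        "n_epochs_total": len(eps),
    }
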