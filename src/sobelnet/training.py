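"""Training: MSE loss, SGD with (Nesterov) momentum, input dropout, metrics.

The optimiser follows the classical momentum recurrence

    v_t     = gamma * v_{t-1} + eta * grad
    theta_t = theta_{t-1} - v_t

with an optional Nesterov look-ahead variant (the default, matching the
training description).  The loss is plain mean squared error between the 0/1
label and the sigmoid score — deliberately not cross-entropy.

Splitting is subject-wise by default: all epochs of a recording stay in one of
train/val/test, which prevents the within-subject leakage an epoch-wise split
would allow.  An epoch-wise split flag exists for comparability but is
leakage-prone and not used by any default pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import ModelParams, backward, forward, init_params
from .sobel import FilterBank, build_filter_bank
from .synth import Epoch


@dataclass
class TrainConfig:
    eta: float = 0.01          # learning rate
    gamma: float = 0.9         # momentum coefficient
    nesterov: bool = True
    dropout_p: float = 0.03    # input dropout probability
    batch_size: int = 64
    n_epochs: int = 40
    seed: int = 0
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)  # train/val/test
    nf: int = 10
    subject_wise: bool = True  # epoch-wise splits leak subject identity

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must be in [0, 1)")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self):
        self.sensitivity = self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan
        self.specificity = self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan
        total = self.tp + self.tn + self.fp + self.fn
        self.accuracy = (self.tp + self.tn) / total if total else math.nan

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def mse_loss(labels, scores) -> float:
    """Mean squared error between 0/1 labels and predicted scores."""
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {scores.shape}")
    if labels.size == 0:
        raise ValueError("mse_loss requires at least one element")
    return float(np.mean((labels - scores) ** 2))


def momentum_step(theta, grad, velocity, cfg: TrainConfig):
    """One SGD-with-momentum update; returns (theta', velocity')."""
    theta, grad, velocity = np.asarray(theta), np.asarray(grad), np.asarray(velocity)
    if theta.shape != grad.shape or theta.shape != velocity.shape:
        raise ValueError("theta, grad and velocity must share a shape")
    v_new = cfg.gamma * velocity + cfg.eta * grad
    if cfg.nesterov:
        # look-ahead form: step with the momentum-corrected velocity
        theta_new = theta - (cfg.gamma * v_new + cfg.eta * grad)
    else:
        theta_new = theta - v_new
    return theta_new, v_new


def apply_input_dropout(x, p: float, rng: np.random.Generator, training: bool):
    """Inverted input dropout: zero entries w.p. p, scale survivors by 1/(1-p)."""
    if not 0 <= p < 1:
        raise ValueError("dropout probability must be in [0, 1)")
    arr = x.values if hasattr(x, "values") else np.asarray(x)
    if not training or p == 0:
        return arr
    mask = rng.random(arr.shape) >= p
    return arr * mask.astype(arr.dtype) / np.asarray(1.0 - p, dtype=arr.dtype)


def classify(scores: np.ndarray) -> np.ndarray:
    """Threshold at 0.5; a score of exactly 0.5 is classified HC (negative)."""
    return (np.asarray(scores) > 0.5).astype(int)


# ---------------------------------------------------------------------------
# data plumbing


def epochs_to_arrays(
    epochs: Sequence[Epoch], standardize: bool = True, dtype=np.float32
):
    """Stack epochs into (B, H, W, 1) plus labels; per-epoch z-scoring by default."""
    if len(epochs) == 0:
        raise ValueError("empty epoch set")
    x = np.stack([np.asarray(e.values, dtype=dtype) for e in epochs])[..., None]
    if standardize:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        sd = x.std(axis=(1, 2, 3), keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    y = np.array([int(e.label) for e in epochs])
    return x, y


def subject_split(
    epochs: Sequence[Epoch],
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> dict[str, str]:
    """Stratified subject-wise split; returns {subject_id: 'train'|'val'|'test'}.

    Subjects of each class are shuffled with the given seed and dealt into the
    three partitions so that every subject's epochs land in exactly one split.
    """
    by_class: dict[int, list[str]] = {}
    label_of: dict[str, int] = {}
    for e in epochs:
        if e.subject_id not in label_of:
            label_of[e.subject_id] = int(e.label)
            by_class.setdefault(int(e.label), []).append(e.subject_id)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in sorted(by_class):
        subs = sorted(by_class[label])
        rng.shuffle(subs)
        n = len(subs)
        n_train = min(max(1, round(fractions[0] * n)), n)
        if n_train == n and n > 1:
            n_train = n - 1
        rest = n - n_train
        n_val = min(max(1 if rest else 0, round(fractions[1] * n)), rest)
        for i, s in enumerate(subs):
            if i < n_train:
                assignment[s] = "train"
            elif i < n_train + n_val:
                assignment[s] = "val"
            else:
                assignment[s] = "test"
    return assignment


def _partition(epochs: Sequence[Epoch], assignment: dict[str, str]):
    parts: dict[str, list[Epoch]] = {"train": [], "val": [], "test": []}
    for e in epochs:
        parts[assignment[e.subject_id]].append(e)
    return parts


def predict_scores(
    params: ModelParams, x: np.ndarray, bank: FilterBank | None = None, chunk: int = 64
) -> np.ndarray:
    """Inference-mode scores in (0, 1); dropout is never applied here."""
    if bank is None:
        bank = build_filter_bank(params.nf)
    out = np.empty(x.shape[0], dtype=float)
    for lo in range(0, x.shape[0], chunk):
        out[lo:lo + chunk] = forward(x[lo:lo + chunk], params, bank).score
    return out


# ---------------------------------------------------------------------------
# training loop


def train(
    epochs: Sequence[Epoch],
    cfg: TrainConfig,
    assignment: dict[str, str] | None = None,
) -> tuple[ModelParams, pd.DataFrame]:
    """Train on a labelled epoch set; returns final params and the learning curve.

    The learning curve has one row per completed epoch with columns
    (epoch, train_loss, train_acc, val_loss, val_acc); train metrics are the
    running averages over the minibatches of that epoch.
    """
    if assignment is None:
        if cfg.subject_wise:
            assignment = subject_split(epochs, cfg.split, cfg.seed)
        else:
            rng = np.random.default_rng(cfg.seed)
            idx = rng.permutation(len(epochs))
            n_tr = round(cfg.split[0] * len(epochs))
            n_val = round(cfg.split[1] * len(epochs))
            assignment = {}
            fake = {}
            for rank, i in enumerate(idx):
                part = "train" if rank < n_tr else "val" if rank < n_tr + n_val else "test"
                fake[i] = part
            epochs = [
                Epoch(values=e.values, label=e.label, subject_id=f"_ew{i}")
                for i, e in enumerate(epochs)
            ]
            assignment = {f"_ew{i}": fake[i] for i in range(len(epochs))}
    parts = _partition(epochs, assignment)
    for name in ("train", "val"):
        labels = {int(e.label) for e in parts[name]}
        if labels != {0, 1}:
            raise ValueError(
                f"{name} split must contain both classes, found labels {sorted(labels)}"
            )

    x_tr, y_tr = epochs_to_arrays(parts["train"])
    x_val, y_val = epochs_to_arrays(parts["val"])
    h, w = x_tr.shape[1], x_tr.shape[2]

    seeds = np.random.SeedSequence(cfg.seed).spawn(3)
    params = init_params(h, w, nf=cfg.nf, seed=seeds[0].generate_state(1)[0] % 2**31)
    bank = build_filter_bank(cfg.nf)
    shuffle_rng = np.random.default_rng(seeds[1])
    dropout_rng = np.random.default_rng(seeds[2])

    velocities = {k: np.zeros_like(v) for k, v in params.tensors().items()}
    rows = []
    n = x_tr.shape[0]
    for ep in range(1, cfg.n_epochs + 1):
        order = shuffle_rng.permutation(n)
        loss_sum = acc_sum = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb = apply_input_dropout(x_tr[idx], cfg.dropout_p, dropout_rng, training=True)
            yb = y_tr[idx]
            out, cache = forward(xb, params, bank, return_cache=True)
            loss_sum += mse_loss(yb, out.score) * len(idx)
            acc_sum += float(np.sum(classify(out.score) == yb))
            d_score = 2.0 * (out.score - yb) / len(idx)
            grads = backward(cache, d_score.astype(out.score.dtype), params)
            for name, g in grads.items():
                theta, vel = momentum_step(
                    getattr(params, name), g.astype(np.float32), velocities[name], cfg
                )
                setattr(params, name, theta.astype(np.float32))
                velocities[name] = vel.astype(np.float32)
        val_scores = predict_scores(params, x_val, bank)
        rows.append(
            {
                "epoch": ep,
                "train_loss": loss_sum / n,
                "train_acc": acc_sum / n,
                "val_loss": mse_loss(y_val, val_scores),
                "val_acc": float(np.mean(classify(val_scores) == y_val)),
            }
        )
    return params, pd.DataFrame(rows)


def evaluate(
    params: ModelParams, epochs: Sequence[Epoch], bank: FilterBank | None = None
) -> EvalMetrics:
    """Confusion-matrix metrics at threshold 0.5 with MDD (label 1) positive."""
    if len(epochs) == 0:
        raise ValueError("evaluate requires a non-empty epoch set")
    x, y = epochs_to_arrays(epochs)
    pred = classify(predict_scores(params, x, bank))
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def filter_count_sweep(
    epochs: Sequence[Epoch], nf_values: Sequence[int], cfg: TrainConfig
) -> pd.DataFrame:
    """Train+evaluate once per filter count, sharing the split and seed."""
    if len(nf_values) == 0:
        raise ValueError("nf_values must be non-empty")
    assignment = subject_split(epochs, cfg.split, cfg.seed)
    parts = _partition(epochs, assignment)
    held_out = parts["test"] or parts["val"]  # tiny cohorts may have no test subjects
    rows = []
    for nf in nf_values:
        cfg_nf = TrainConfig(**{**cfg.__dict__, "nf": int(nf)})
        params, _ = train(epochs, cfg_nf, assignment=assignment)
        metrics = evaluate(params, held_out)
        rows.append({"nf": int(nf), **metrics.as_dict()})
    return pd.DataFrame(rows)
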