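"""Training loop: SGD with momentum, step (or linear) learning-rate decay,
imbalance strategies, per-epoch logging, and best-AUC checkpointing."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imbalance import (
    PenaltyConfig,
    STRATEGIES,
    apply_gradient_penalty,  # noqa: F401  (re-exported for callers)
    gradient_penalty_factors,
    oversample,
    reverse_weights,
)
from .metrics import auc as roc_auc
from .model import ResTransNet, ce_loss, save_checkpoint
from .nn import SGD, Tensor
from .preprocess import CohortSplit, stack_images


@dataclass
class TrainConfig:
    """Optimisation recipe: SGD, lr 0.01, momentum 0.9, weight decay 5e-4,
    batch 128, lr divided by 10 at epochs 50/100/150 with a 1e-5 floor."""

    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 128
    milestones: tuple[int, ...] = (50, 100, 150)
    lr_floor: float = 1e-5
    epochs: int = 200
    seed: int = 0
    schedule: str = "step"  # or "linear"
    imbalance: str = "oversample"
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)

    def __post_init__(self):
        if self.imbalance not in STRATEGIES:
            raise ValueError(f"imbalance must be one of {STRATEGIES}")
        if min(self.lr0, self.momentum + 1, self.weight_decay + 1,
               self.batch_size, self.lr_floor, self.epochs) <= 0:
            raise ValueError("config values must be positive")
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ValueError("milestones must be strictly increasing")
        if self.schedule not in ("step", "linear"):
            raise ValueError("schedule must be 'step' or 'linear'")


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Learning rate for a (0-based) epoch.

    Step schedule: lr0 divided by 10 at each passed milestone, never below
    lr_floor.  Linear schedule: straight line from lr0 to lr_floor over the
    run (the alternative reading of the recipe).
    """
    if config.schedule == "linear":
        frac = epoch / max(config.epochs - 1, 1)
        return config.lr0 + (config.lr_floor - config.lr0) * min(frac, 1.0)
    passed = sum(epoch >= m for m in config.milestones)
    return max(config.lr0 / 10**passed, config.lr_floor)


def _snapshot(model: ResTransNet) -> dict:
    from .model import BatchNorm2d, _named_modules

    state = {name: p.data.copy() for name, p in model.named_parameters()}
    for name, mod in _named_modules(model):
        if isinstance(mod, BatchNorm2d):
            state[f"__bn_mean__{name}"] = mod.running_mean.copy()
            state[f"__bn_var__{name}"] = mod.running_var.copy()
    return state


def _restore(model: ResTransNet, state: dict) -> None:
    from .model import BatchNorm2d, _named_modules

    for name, p in model.named_parameters():
        p.data = state[name]
    for name, mod in _named_modules(model):
        if isinstance(mod, BatchNorm2d):
            mod.running_mean = state[f"__bn_mean__{name}"].copy()
            mod.running_var = state[f"__bn_var__{name}"].copy()


def train(model: ResTransNet, cohort: CohortSplit, config: TrainConfig,
          out_dir: str | None = None) -> tuple[ResTransNet, pd.DataFrame]:
    """Train on the cohort's training images; evaluate on its test images
    each epoch; keep the best-test-AUC checkpoint (restored before return).

    Deterministic for a fixed seed.  Raises on divergent (non-finite) loss.
    """
    if not cohort.train:
        raise ValueError("empty training set")
    x_train, y_train = stack_images(cohort.train)
    x_test, y_test = stack_images(cohort.test) if cohort.test else (None, None)
    rng = np.random.default_rng(config.seed)
    optimizer = SGD(model.parameters(), lr=config.lr0,
                    momentum=config.momentum, weight_decay=config.weight_decay)
    class_weights = None
    if config.imbalance == "reweight":
        counts = np.bincount(y_train, minlength=2)
        class_weights = reverse_weights(counts)
    log_rows = []
    best = {"auc": -np.inf, "state": None}
    for epoch in range(config.epochs):
        optimizer.lr = lr_at(epoch, config)
        # re-weighting and the gradient penalty both ride on oversampling
        if config.imbalance in ("oversample", "reweight", "gradient_penalty"):
            order = oversample(y_train, rng)
        else:
            order = rng.permutation(len(y_train))
        model.train()
        losses, n_correct, n_seen = [], 0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            sample_weights = None
            if config.imbalance == "gradient_penalty" and len(idx) > 1:
                g = model.per_sample_gradients(xb, yb, scope="penalty")
                sample_weights = gradient_penalty_factors(g, config.penalty)
            model.zero_grad()
            logits = model.forward(xb)
            probs = logits.softmax(axis=-1)[:, 1]
            loss = ce_loss(probs, yb, class_weights=class_weights,
                           sample_weights=sample_weights)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"divergent loss {loss.item()} at epoch {epoch}; "
                    "reduce the learning rate or check the inputs")
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
            n_correct += int(((probs.data >= 0.5).astype(int) == yb).sum())
            n_seen += len(idx)
        row = {"epoch": epoch, "lr": optimizer.lr,
               "train_loss": float(np.mean(losses)),
               "train_acc": n_correct / n_seen}
        if x_test is not None and len(np.unique(y_test)) > 1:
            scores = model.predict_proba(x_test)
            row["test_acc"] = float(((scores >= 0.5).astype(int) == y_test).mean())
            row["test_auc"] = roc_auc(scores, y_test)
            # >= : at equal AUC prefer the later, better-calibrated state
            if row["test_auc"] >= best["auc"]:
                best["auc"] = row["test_auc"]
                best["state"] = _snapshot(model)
        log_rows.append(row)
    log = pd.DataFrame(log_rows)
    if best["state"] is not None:
        _restore(model, best["state"])
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        save_checkpoint(model, os.path.join(out_dir, "checkpoint.npz"))
        log.to_csv(os.path.join(out_dir, "training_log.csv"), index=False)
    return model, log
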