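"""Model training: single runs and cosine-annealing warm restarts.

A warm-restart run divides training into cycles of ``T`` epochs.  Within a
cycle the learning rate anneals from ``gamma_max`` down toward ``gamma_min``
along a half cosine,

    gamma(t) = gamma_min + (gamma_max - gamma_min) * (1 + cos(pi * t / T)) / 2,

and resets to ``gamma_max`` at each cycle boundary (epoch ``e`` uses
``t = e mod T``).  Each reset kicks the trajectory out of its current local
minimum; the best-validation-accuracy parameters found within each cycle are
harvested as one snapshot, so a single run yields ``epochs / T`` candidate
ensemble members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import nn
from .arch import ArchitectureSpec, SequenceClassifier, build_model


@dataclass(frozen=True)
class WarmRestartSchedule:
    """Cyclic cosine-annealing learning-rate schedule.

    ``gamma_min``/``gamma_max`` bound the rate; ``T`` is epochs per cycle.
    A degenerate schedule with ``gamma_min == gamma_max`` is permitted and
    trains at a constant rate.
    """

    gamma_min: float
    gamma_max: float
    T: int

    def __post_init__(self) -> None:
        if self.gamma_min < 0 or self.gamma_max < self.gamma_min:
            raise ValueError("need 0 <= gamma_min <= gamma_max")
        if self.T < 1:
            raise ValueError("T must be a positive integer")


def learning_rate(schedule: WarmRestartSchedule, t_cur: float) -> float:
    """Evaluate the cosine annealing curve at epoch ``t_cur`` within a cycle."""
    if not 0 <= t_cur <= schedule.T:
        raise ValueError(f"t_cur={t_cur} outside [0, {schedule.T}]")
    return schedule.gamma_min + 0.5 * (schedule.gamma_max - schedule.gamma_min) * (
        1.0 + math.cos(math.pi * t_cur / schedule.T))


def schedule_trace(schedule: WarmRestartSchedule, epochs: int) -> np.ndarray:
    """Per-epoch learning rates over a run (sawtooth across cycles)."""
    return np.array([learning_rate(schedule, e % schedule.T) for e in range(epochs)])


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for one training run.

    ``base_lr`` applies when no schedule is given (the optimizer's common
    default of 1e-3); with a schedule, the cosine curve drives the rate.
    The validation split is stratified and carved once, by ``seed``.
    """

    epochs: int
    batch_size: int = 32
    base_lr: float = 1e-3
    validation_fraction: float = 0.2
    seed: int = 0
    schedule: WarmRestartSchedule | None = None
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.schedule is not None and self.epochs % self.schedule.T != 0:
            raise ValueError(
                f"epochs={self.epochs} must be a multiple of the cycle "
                f"length T={self.schedule.T}")


@dataclass(frozen=True)
class SnapshotMember:
    """Parameters harvested at the best-validation epoch of one cycle."""

    cycle: int
    state: list[np.ndarray]
    val_accuracy: float
    epoch: int            # global epoch index of the harvested parameters


@dataclass
class SnapshotSet:
    """One snapshot per completed warm-restart cycle, plus the run history."""

    arch_spec: ArchitectureSpec
    input_length: int
    members: list[SnapshotMember]
    history: pd.DataFrame

    def __post_init__(self) -> None:
        cycles = [m.cycle for m in self.members]
        if any(b <= a for a, b in zip(cycles, cycles[1:])):
            raise ValueError("cycle indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.members)

    def classifier(self, index: int) -> SequenceClassifier:
        """Materialize snapshot ``index`` as a standalone classifier."""
        model = build_model(self.arch_spec, seed=0, input_length=self.input_length)
        model.set_state(self.members[index].state)
        return model


@dataclass
class TrainResult:
    model: SequenceClassifier
    history: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float


def _validate_data(X: np.ndarray, y: np.ndarray) -> None:
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} samples but {y.shape[0]} labels")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")


def _split(X, y, config):
    return train_test_split(X, y, test_size=config.validation_fraction,
                            random_state=config.seed, stratify=y)


def _accuracy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((probs >= 0.5) == y))


def _run(model: SequenceClassifier, X_tr, y_tr, X_val, y_val,
         config: TrainingConfig, harvest: bool):
    """Shared epoch loop.  With ``harvest`` the schedule is mandatory and the
    best-within-cycle parameters are collected; otherwise the single best
    epoch over the whole run is retained."""
    rng = np.random.default_rng(config.seed)
    opt = nn.RMSProp(model.params(), rho=config.rmsprop_rho, eps=config.rmsprop_eps)
    n = X_tr.shape[0]
    rows = []
    best_state, best_acc, best_epoch = None, -1.0, -1
    cyc_state, cyc_acc, cyc_epoch = None, -1.0, -1
    members: list[SnapshotMember] = []
    T = config.schedule.T if config.schedule else None
    for epoch in range(config.epochs):
        lr = (learning_rate(config.schedule, epoch % T)
              if config.schedule else config.base_lr)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = model.forward(X_tr[idx], train=True, rng=rng)
            loss, dlogits = nn.bce_with_logits(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss * len(idx))
            correct += int(((logits >= 0.0) == y_tr[idx]).sum())
        val_logits = model.forward(X_val)
        val_loss, _ = nn.bce_with_logits(val_logits, y_val)
        val_acc = float(np.mean((val_logits >= 0.0) == y_val))
        rows.append({"epoch": epoch, "lr": lr,
                     "train_loss": sum(losses) / n, "train_acc": correct / n,
                     "val_loss": val_loss, "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc, best_epoch, best_state = val_acc, epoch, model.get_state()
        if harvest:
            if val_acc > cyc_acc:
                cyc_acc, cyc_epoch, cyc_state = val_acc, epoch, model.get_state()
            if (epoch + 1) % T == 0:
                members.append(SnapshotMember(cycle=len(members),
                                              state=cyc_state,
                                              val_accuracy=cyc_acc,
                                              epoch=cyc_epoch))
                cyc_state, cyc_acc, cyc_epoch = None, -1.0, -1
    history = pd.DataFrame(rows)
    return history, best_state, best_acc, best_epoch, members


def train_single(model: SequenceClassifier, X: np.ndarray, y: np.ndarray,
                 config: TrainingConfig,
                 validation: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> TrainResult:
    """Train one model, retaining the best-validation-accuracy epoch.

    ``validation`` supplies an explicit held-out split; otherwise a seeded
    stratified split of ``validation_fraction`` is carved from ``(X, y)``.
    The returned model carries the best epoch's parameters; ``history`` has
    one row per epoch with train/validation loss and accuracy.
    """
    _validate_data(X, y)
    if validation is None:
        X_tr, X_val, y_tr, y_val = _split(X, y, config)
    else:
        X_tr, y_tr = X, y
        X_val, y_val = validation
    history, best_state, best_acc, best_epoch, _ = _run(
        model, X_tr, y_tr, X_val, y_val, config, harvest=False)
    model.set_state(best_state)
    return TrainResult(model=model, history=history,
                       best_epoch=best_epoch, best_val_accuracy=best_acc)


def train_with_warm_restarts(model: SequenceClassifier, X: np.ndarray,
                             y: np.ndarray, config: TrainingConfig,
                             validation: tuple[np.ndarray, np.ndarray] | None = None
                             ) -> SnapshotSet:
    """Warm-restart training harvesting one snapshot per cosine cycle."""
    if config.schedule is None:
        raise ValueError("warm-restart training requires config.schedule")
    _validate_data(X, y)
    if validation is None:
        X_tr, X_val, y_tr, y_val = _split(X, y, config)
    else:
        X_tr, y_tr = X, y
        X_val, y_val = validation
    history, _, _, _, members = _run(
        model, X_tr, y_tr, X_val, y_val, config, harvest=True)
    return SnapshotSet(arch_spec=model.spec,
                       input_length=model.input_length or X.shape[1],
                       members=members, history=history)
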