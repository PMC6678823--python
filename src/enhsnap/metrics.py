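"""Evaluation: confusion-matrix metrics, ROC/AUC, and k-fold cross-validation.

The positive class is the enhancer (task layer 1) or the strong enhancer
(task layer 2).  With confusion counts TP/FP/TN/FN,

    Sens = TP / (TP + FN)               Spec = TN / (TN + FP)
    Acc  = (TP + TN) / total
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 when any marginal is zero (the standard convention for a
degenerate predictor); Sens/Spec likewise fall back to 0 on an empty
denominator.  The ROC curve comes from a threshold sweep over the scores and
AUC from the trapezoidal rule, which coincides with the rank statistic
P(score+ > score-) with ties counted half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass
class MetricsReport:
    """Sens/Spec/Acc/MCC plus optional ROC curve and AUC."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None
    roc: np.ndarray | None = None      # (k, 2) columns (FPR, TPR)
    counts: ConfusionCounts | None = None

    def to_row(self) -> dict:
        """Percent-scaled tidy row (Acc/Sn/Sp/AUC in %, MCC raw)."""
        return {
            "Acc(%)": round(100 * self.accuracy, 4),
            "MCC": round(self.mcc, 6),
            "Sn(%)": round(100 * self.sensitivity, 4),
            "Sp(%)": round(100 * self.specificity, 4),
            "AUC(%)": round(100 * self.auc, 4) if self.auc is not None else "",
        }


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return v.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Four-cell cross-tabulation of binary truth vs. prediction."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sens/Spec/Acc/MCC from confusion counts (no ROC/AUC)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from empty counts")
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    acc = (c.TP + c.TN) / c.total
    denom = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    mcc = ((c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)) if denom else 0.0
    return MetricsReport(sensitivity=sens, specificity=spec, accuracy=acc,
                         mcc=mcc, counts=c)


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from (0,0) to (1,1) and trapezoidal AUC."""
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined: y_true contains a single class")
    fpr, tpr, _ = roc_curve(y_true, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def evaluate_predictions(y_true, y_pred, scores=None) -> MetricsReport:
    """Full report from voted labels plus (optionally) continuous scores."""
    report = metrics(confusion(y_true, y_pred))
    if scores is not None:
        report.roc, report.auc = roc_auc(y_true, scores)
    return report


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    fold_assignments: np.ndarray       # fold index per sample

    def to_frame(self) -> pd.DataFrame:
        rows = [r.to_row() for r in self.fold_reports]
        rows.append(self.pooled.to_row())
        idx = [f"fold{i}" for i in range(len(self.fold_reports))] + ["pooled"]
        return pd.DataFrame(rows, index=idx)


def cross_validate(arch, X: np.ndarray, y: np.ndarray, k: int = 5,
                   config=None, max_members: int = 5,
                   model_factory=None) -> CrossValidationResult:
    """Stratified k-fold cross-validation of the full training recipe.

    Each fold trains a fresh model on the remaining folds (warm restarts with
    snapshot-ensemble selection when ``config.schedule`` is set, otherwise a
    plain best-epoch run) and scores the held-out fold.  Pooled metrics come
    from the pooled confusion counts and pooled scores, matching how a single
    summary row is reported.  ``model_factory(fold_seed)`` may inject an
    arbitrary classifier exposing ``predict_proba`` (it is then used as-is,
    untrained) — useful for calibration checks with degenerate predictors.
    """
    from .arch import build_model
    from .train import TrainingConfig, train_single, train_with_warm_restarts
    from .ensemble import select_members, vote

    y = _check_binary(y, "y")
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class count {counts.min()}")
    if config is None:
        config = TrainingConfig(epochs=10)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    assignments = np.full(len(y), -1)
    fold_reports = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    pooled_scores = np.zeros(len(y))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assignments[te] = fold
        fold_seed = config.seed + 1000 * (fold + 1)
        if model_factory is not None:
            predictor = model_factory(fold_seed)
            scores = predictor.predict_proba(X[te])
            labels = (scores >= 0.5).astype(int)
        else:
            fold_cfg = TrainingConfig(
                epochs=config.epochs, batch_size=config.batch_size,
                base_lr=config.base_lr,
                validation_fraction=config.validation_fraction,
                seed=fold_seed, schedule=config.schedule,
                rmsprop_rho=config.rmsprop_rho, rmsprop_eps=config.rmsprop_eps)
            model = build_model(arch, seed=fold_seed, input_length=X.shape[1])
            if config.schedule is not None:
                X_tr, X_val, y_tr, y_val = train_test_split(
                    X[tr], y[tr], test_size=config.validation_fraction,
                    random_state=fold_seed, stratify=y[tr])
                snaps = train_with_warm_restarts(
                    model, X_tr, y_tr, fold_cfg, validation=(X_val, y_val))
                ens = select_members(snaps, X_val, y_val, max_members=max_members)
                labels, scores = ens.predict(X[te])
            else:
                result = train_single(model, X[tr], y[tr], fold_cfg)
                scores = result.model.predict_proba(X[te])
                labels = (scores >= 0.5).astype(int)
        pooled_scores[te] = scores
        c = confusion(y[te], labels)
        pooled_counts = pooled_counts + c
        fold_reports.append(evaluate_predictions(y[te], labels, scores))
    pooled = metrics(pooled_counts)
    pooled.roc, pooled.auc = roc_auc(y, pooled_scores)
    return CrossValidationResult(fold_reports=fold_reports, pooled=pooled,
                                 fold_assignments=assignments)
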