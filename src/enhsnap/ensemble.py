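"""Snapshot-member selection and majority-vote aggregation.

An ensemble's label is the majority vote of its members' thresholded
predictions; its continuous score (used for ROC/AUC) is the mean member
probability.  Even-split votes are broken by comparing the mean probability
against the threshold.  Member subsets are chosen on validation data:
exhaustively when the candidate-subset count is small, by greedy forward
selection otherwise.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arch import SequenceClassifier
from .train import SnapshotSet

EXHAUSTIVE_SUBSET_LIMIT = 4096


def vote(prob_matrix: np.ndarray, threshold: float = 0.5
         ) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate an ``(M, N)`` member-probability matrix.

    Returns (majority-vote labels, mean-probability scores); an even vote
    split falls back to comparing the mean score with the threshold.
    """
    P = np.atleast_2d(prob_matrix)
    M = P.shape[0]
    scores = P.mean(axis=0)
    positives = (P >= threshold).sum(axis=0)
    labels = np.where(2 * positives > M, 1,
                      np.where(2 * positives < M, 0,
                               (scores >= threshold).astype(int)))
    return labels.astype(int), scores


@dataclass
class EnsembleModel:
    """A fixed set of classifiers aggregated by majority vote.

    ``selection`` records how the members were chosen (snapshot cycles,
    validation accuracy) for the run manifest.
    """

    members: list[SequenceClassifier]
    threshold: float = 0.5
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("an ensemble needs at least one member")

    def __len__(self) -> int:
        return len(self.members)

    def member_probabilities(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return vote(self.member_probabilities(X), self.threshold)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.member_probabilities(X).mean(axis=0)

    def save(self, directory: str | Path) -> Path:
        """Write member checkpoints plus a JSON manifest; returns its path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, m in enumerate(self.members):
            p = directory / f"member_{i}.npz"
            m.save(p)
            paths.append(p.name)
        manifest = {"members": paths, "threshold": self.threshold,
                    "aggregation": "majority-vote/mean-probability",
                    "selection": self.selection}
        mpath = directory / "ensemble_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2) + "\n")
        return mpath

    @classmethod
    def load(cls, manifest_path: str | Path) -> "EnsembleModel":
        manifest_path = Path(manifest_path)
        manifest = json.loads(manifest_path.read_text())
        members = [SequenceClassifier.load(manifest_path.parent / name)
                   for name in manifest["members"]]
        return cls(members=members, threshold=manifest["threshold"],
                   selection=manifest.get("selection", {}))


def predict_ensemble(ens: EnsembleModel, X: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Voted labels and mean-probability scores for encoded samples."""
    return ens.predict(X)


def _voted_accuracy(P: np.ndarray, y: np.ndarray, threshold: float) -> float:
    labels, _ = vote(P, threshold)
    return float(np.mean(labels == y))


def select_members(snapshots: SnapshotSet, X_val: np.ndarray, y_val: np.ndarray,
                   max_members: int = 5, threshold: float = 0.5) -> EnsembleModel:
    """Choose the snapshot subset with the best voted validation accuracy.

    All subsets of size 1..``max_members`` are scored when their count is at
    most ``EXHAUSTIVE_SUBSET_LIMIT``; otherwise greedy forward selection adds
    the member that most improves voted accuracy.  Ties keep the first
    (smallest, earliest-cycle) subset encountered.
    """
    M = len(snapshots)
    if M == 0:
        raise ValueError("empty snapshot set")
    max_members = min(max_members, M)
    classifiers = [snapshots.classifier(i) for i in range(M)]
    P = np.stack([c.predict_proba(X_val) for c in classifiers])

    n_subsets = sum(len(list(itertools.combinations(range(M), k)))
                    for k in range(1, max_members + 1)) if M <= 20 else None
    best_subset, best_acc = None, -1.0
    if n_subsets is not None and n_subsets <= EXHAUSTIVE_SUBSET_LIMIT:
        strategy = "exhaustive"
        for k in range(1, max_members + 1):
            for subset in itertools.combinations(range(M), k):
                acc = _voted_accuracy(P[list(subset)], y_val, threshold)
                if acc > best_acc:
                    best_acc, best_subset = acc, subset
    else:
        strategy = "greedy-forward"
        chosen: list[int] = []
        remaining = list(range(M))
        while remaining and len(chosen) < max_members:
            cand_best, cand_acc = None, -1.0
            for i in remaining:
                acc = _voted_accuracy(P[chosen + [i]], y_val, threshold)
                if acc > cand_acc:
                    cand_acc, cand_best = acc, i
            if chosen and cand_acc <= best_acc:
                break
            chosen.append(cand_best)
            remaining.remove(cand_best)
            best_acc = cand_acc
        best_subset = tuple(chosen)

    members = [classifiers[i] for i in best_subset]
    selection = {
        "strategy": strategy,
        "cycles": [int(snapshots.members[i].cycle) for i in best_subset],
        "member_epochs": [int(snapshots.members[i].epoch) for i in best_subset],
        "validation_accuracy": best_acc,
        "candidates": M,
        "max_members": max_members,
    }
    return EnsembleModel(members=members, threshold=threshold, selection=selection)
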