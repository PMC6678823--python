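"""End-to-end experiment orchestration for the two-layer enhancer tasks.

A run encodes the training sequences, carves a seeded stratified validation
split, trains one model with warm restarts, harvests the per-cycle
snapshots, selects a majority-vote ensemble on the validation split, and
evaluates both the best single snapshot and the ensemble on held-out test
data — the Single/Ensemble reporting convention of the original benchmark
studies.  Everything is deterministic given the experiment seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from .arch import build_model, get_architecture
from .encoding import encode_dataset, read_fasta, read_label_table
from .ensemble import EnsembleModel, select_members
from .metrics import MetricsReport, evaluate_predictions
from .synthetic import SyntheticSpec, generate
from .train import (SnapshotSet, TrainingConfig, WarmRestartSchedule,
                    train_with_warm_restarts)


@dataclass(frozen=True)
class DataPaths:
    """FASTA inputs for one layer: either one FASTA per class, or a single
    FASTA plus a two-column (id, label) TSV."""

    positive_fasta: str | None = None
    negative_fasta: str | None = None
    fasta: str | None = None
    labels: str | None = None

    def __post_init__(self) -> None:
        two_file = self.positive_fasta is not None and self.negative_fasta is not None
        tabular = self.fasta is not None and self.labels is not None
        if two_file == tabular:
            raise ValueError("supply either positive+negative FASTA or FASTA+labels TSV")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment.

    ``layer`` selects the task (1: enhancer vs. non-enhancer, 2: strong vs.
    weak).  ``train_data``/``test_data`` point at files; both ``None`` means
    the bundled synthetic generator supplies them (``synthetic`` sizes the
    training set, ``n_test_per_class`` the held-out set).
    """

    layer: int = 1
    architecture: str = "gru_2x16_dense16"
    training: TrainingConfig = field(default_factory=lambda: TrainingConfig(
        epochs=60, seed=0,
        schedule=WarmRestartSchedule(gamma_min=1e-4, gamma_max=0.003, T=20)))
    max_members: int = 5
    threshold: float = 0.5
    train_data: DataPaths | None = None
    test_data: DataPaths | None = None
    synthetic: SyntheticSpec | None = None
    n_test_per_class: int = 50
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer not in (1, 2):
            raise ValueError("layer must be 1 or 2")
        get_architecture(self.architecture)   # raises on unknown name
        if (self.train_data is None) != (self.test_data is None):
            raise ValueError("supply both train_data and test_data, or neither")


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    snapshots: SnapshotSet
    ensemble: EnsembleModel
    single_report: MetricsReport
    ensemble_report: MetricsReport
    metrics_table: pd.DataFrame
    output_dir: Path | None


def _load_layer(paths: DataPaths) -> tuple[list, np.ndarray]:
    if paths.positive_fasta is not None:
        pos = read_fasta(paths.positive_fasta)
        neg = read_fasta(paths.negative_fasta)
        seqs = pos + neg
        labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    else:
        seqs = read_fasta(paths.fasta)
        table = read_label_table(paths.labels)
        missing = [s.id for s in seqs if s.id not in table]
        if missing:
            raise ValueError(f"no label for sequence ids: {missing[:5]}")
        labels = np.array([table[s.id] for s in seqs], dtype=int)
    return seqs, labels


def _check_paths(paths: DataPaths | None) -> None:
    if paths is None:
        return
    for p in (paths.positive_fasta, paths.negative_fasta, paths.fasta, paths.labels):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")


def _experiment_data(config: ExperimentConfig):
    if config.train_data is not None:
        _check_paths(config.train_data)
        _check_paths(config.test_data)
        train_seqs, train_labels = _load_layer(config.train_data)
        test_seqs, test_labels = _load_layer(config.test_data)
    else:
        spec = config.synthetic or SyntheticSpec(seed=config.seed)
        train_ds = generate(spec)
        test_spec = SyntheticSpec(
            n_per_class=2 * config.n_test_per_class, length=spec.length,
            motif=spec.motif, copies_positive=spec.copies_positive,
            copies_strong=spec.copies_strong, background=spec.background,
            seed=spec.seed + 900_001)
        test_ds = generate(test_spec)
        train_seqs, train_labels = train_ds.layer(config.layer)
        test_seqs, test_labels = test_ds.layer(config.layer)
    X_train, y_train = encode_dataset(train_seqs, train_labels.tolist())
    X_test, y_test = encode_dataset(test_seqs, test_labels.tolist())
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test sequence lengths differ")
    return X_train, y_train, X_test, y_test


def _config_to_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    if config.synthetic is not None:
        d["synthetic"]["motif"] = np.asarray(config.synthetic.motif).tolist()
    return d


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run encode → warm-restart train → select ensemble → evaluate.

    Writes, when ``output_dir`` is set: the resolved config (YAML), the
    per-epoch history (CSV), every snapshot checkpoint, the ensemble
    manifest, Single/Ensemble metrics (TSV + JSON) and ROC points (CSV).
    Rerunning with the same config is byte-identical on the metrics tables.
    """
    X_train, y_train, X_test, y_test = _experiment_data(config)

    tcfg = config.training
    X_tr, X_val, y_tr, y_val = train_test_split(
        X_train, y_train, test_size=tcfg.validation_fraction,
        random_state=tcfg.seed, stratify=y_train)
    model = build_model(config.architecture, seed=config.seed,
                        input_length=X_train.shape[1])
    snapshots = train_with_warm_restarts(model, X_tr, y_tr, tcfg,
                                         validation=(X_val, y_val))
    ens = select_members(snapshots, X_val, y_val,
                         max_members=config.max_members,
                         threshold=config.threshold)

    best_idx = int(np.argmax([m.val_accuracy for m in snapshots.members]))
    single = snapshots.classifier(best_idx)
    single_scores = single.predict_proba(X_test)
    single_labels = (single_scores >= config.threshold).astype(int)
    single_report = evaluate_predictions(y_test, single_labels, single_scores)

    ens_labels, ens_scores = ens.predict(X_test)
    ensemble_report = evaluate_predictions(y_test, ens_labels, ens_scores)

    table = pd.DataFrame([single_report.to_row(), ensemble_report.to_row()],
                         index=["Single", "Ensemble"])
    table.index.name = "Type"

    outdir = None
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(_config_to_dict(config), sort_keys=False))
        snapshots.history.to_csv(outdir / "history.csv", index=False)
        for i in range(len(snapshots)):
            snapshots.classifier(i).save(outdir / f"snapshot_cycle{i}.npz")
        single.save(outdir / "best_single.npz")
        ens.save(outdir)
        table.to_csv(outdir / "metrics.tsv", sep="\t")
        (outdir / "metrics.json").write_text(json.dumps({
            "layer": config.layer,
            "architecture": config.architecture,
            "single": single_report.to_row(),
            "ensemble": ensemble_report.to_row(),
            "ensemble_members": len(ens),
            "selection": ens.selection,
        }, indent=2) + "\n")
        np.savetxt(outdir / "roc_single.csv", single_report.roc,
                   delimiter=",", header="fpr,tpr", comments="")
        np.savetxt(outdir / "roc_ensemble.csv", ensemble_report.roc,
                   delimiter=",", header="fpr,tpr", comments="")

    return ExperimentResult(config=config, snapshots=snapshots, ensemble=ens,
                            single_report=single_report,
                            ensemble_report=ensemble_report,
                            metrics_table=table, output_dir=outdir)


def predict_cascade(layer1_model, layer2_model, X: np.ndarray,
                    threshold: float = 0.5) -> pd.DataFrame:
    """Optional two-stage composition: layer 2 scores layer-1 positives only.

    Off the main evaluation path (the two layers are independent
    experiments); provided as a convenience for three-way calls.  Returns
    per-sample ``call`` in {non-enhancer, weak enhancer, strong enhancer}
    with both stages' scores (layer-2 score is NaN for layer-1 negatives).
    """
    def _score(model, Xs):
        probs = model.predict_proba(Xs)
        return probs if isinstance(probs, np.ndarray) else np.asarray(probs)

    s1 = _score(layer1_model, X)
    is_enh = s1 >= threshold
    s2 = np.full(X.shape[0], np.nan)
    if is_enh.any():
        s2[is_enh] = _score(layer2_model, X[is_enh])
    call = np.where(~is_enh, "non-enhancer",
                    np.where(np.nan_to_num(s2) >= threshold,
                             "strong enhancer", "weak enhancer"))
    return pd.DataFrame({"layer1_score": s1, "layer2_score": s2, "call": call})


def predict_fasta(model_path: str | Path, fasta_path: str | Path,
                  threshold: float = 0.5) -> pd.DataFrame:
    """Score a FASTA file with a checkpoint (.npz) or ensemble manifest (.json).

    Returns one row per record, in file order, with the predicted label and
    continuous score.  Sequence lengths must match the model's training
    length — a fixed-length model cannot score other lengths.
    """
    model_path = Path(model_path)
    if model_path.suffix == ".json":
        predictor = EnsembleModel.load(model_path)
        expected = predictor.members[0].input_length
    else:
        from .arch import SequenceClassifier
        predictor = SequenceClassifier.load(model_path)
        expected = predictor.input_length
    seqs = read_fasta(fasta_path)
    X, _ = encode_dataset(seqs)
    if expected is not None and X.shape[0] and X.shape[1] != expected:
        raise ValueError(
            f"model expects {expected}-bp sequences but the input has "
            f"{X.shape[1]}-bp records; a fixed-length model cannot score "
            f"sequences of another length")
    if isinstance(predictor, EnsembleModel):
        labels, scores = predictor.predict(X)
    else:
        scores = predictor.predict_proba(X)
        labels = (scores >= threshold).astype(int)
    return pd.DataFrame({"id": [s.id for s in seqs],
                         "label": labels.astype(int),
                         "score": scores})
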