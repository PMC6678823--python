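"""Declarative architecture specs and model construction.

The classifier family is small: an optional Conv1D(+max-pool) front end that
shortens the 200-bp input, one or two (bi)GRU layers whose final hidden state
summarizes the sequence, an optional ReLU dense layer, and a single sigmoid
output unit trained with binary cross-entropy.  ``catalog()`` enumerates the
configurations explored for the enhancer tasks, named by their topology
(e.g. ``gru_2x16_dense16`` = two 16-unit GRU layers plus a 16-unit dense
layer); regularized variants carry ``_dpXX`` / ``_l1l2`` suffixes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .encoding import N_CHANNELS


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a classifier graph.

    ``kind`` is one of conv1d / maxpool1d / gru / dense / dropout.  ``size``
    is channels (conv), units (gru/dense); ``kernel`` / ``pool`` are the
    conv / pooling window widths; ``dropout_rate`` on a gru/dense layer is
    applied to that layer's inputs.
    """

    kind: str
    size: int | None = None
    kernel: int | None = None
    pool: int | None = None
    stride: int = 1
    bidirectional: bool = False
    dropout_rate: float = 0.0
    l1: float = 0.0
    l2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("conv1d", "maxpool1d", "gru", "dense", "dropout"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv1d" and (not self.kernel or not self.size):
            raise ValueError("conv1d requires kernel and size")
        if self.kind == "maxpool1d" and not self.pool:
            raise ValueError("maxpool1d requires pool")
        if self.kind in ("gru", "dense") and not self.size:
            raise ValueError(f"{self.kind} requires size")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A named, ordered layer stack ending in one sigmoid output unit.

    The output unit and the binary cross-entropy loss are implicit — every
    catalog model is a binary classifier.
    """

    name: str
    layers: tuple[LayerSpec, ...]

    def __post_init__(self) -> None:
        if not any(l.kind == "gru" for l in self.layers):
            raise ValueError("catalog architectures contain at least one GRU layer")

    def to_dict(self) -> dict:
        return {"name": self.name, "layers": [asdict(l) for l in self.layers]}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(name=d["name"],
                   layers=tuple(LayerSpec(**l) for l in d["layers"]))


def _gru_stack(name: str, n_gru: int, units: int, dense: int | None,
               conv: bool = False, bidirectional: bool = False,
               dropout: float = 0.0, l1l2: float = 0.0) -> ArchitectureSpec:
    layers: list[LayerSpec] = []
    if conv:
        layers.append(LayerSpec("conv1d", size=16, kernel=9, l1=l1l2, l2=l1l2))
        layers.append(LayerSpec("maxpool1d", pool=2))
    for _ in range(n_gru):
        layers.append(LayerSpec("gru", size=units, bidirectional=bidirectional,
                                dropout_rate=dropout, l1=l1l2, l2=l1l2))
    if dense:
        layers.append(LayerSpec("dense", size=dense, dropout_rate=dropout,
                                l1=l1l2, l2=l1l2))
    return ArchitectureSpec(name=name, layers=tuple(layers))


def catalog() -> dict[str, ArchitectureSpec]:
    """All explored architectures, from smallest single-GRU upward.

    The plain entries are the unregularized base configurations; ``_dpXX``
    adds input dropout at rate 0.XX to every GRU/dense layer and ``_l1l2``
    adds 3e-5 L1+L2 weight penalties — the fine-tuning grid.  The two
    workhorses are ``gru_2x16_dense16`` (recurrent-only) and
    ``conv_bigru_2x16_dense8`` (conv front end + bidirectional GRUs).
    """
    specs = [
        _gru_stack("gru_1x8", 1, 8, None),
        _gru_stack("gru_1x16", 1, 16, None),
        _gru_stack("gru_2x16", 2, 16, None),
        _gru_stack("gru_2x16_dense16", 2, 16, 16),
        _gru_stack("bigru_1x16_dense16", 1, 16, 16, bidirectional=True),
        _gru_stack("conv_gru_2x8_dense8", 2, 8, 8, conv=True),
        _gru_stack("conv_bigru_2x8_dense8", 2, 8, 8, conv=True, bidirectional=True),
        _gru_stack("conv_bigru_2x16_dense8", 2, 16, 8, conv=True, bidirectional=True),
    ]
    for rate in (0.1, 0.2, 0.3, 0.4):
        specs.append(_gru_stack(f"gru_2x16_dense16_dp{int(rate * 10):02d}",
                                2, 16, 16, dropout=rate))
    specs.append(_gru_stack("conv_bigru_2x16_dense8_dp06", 2, 16, 8,
                            conv=True, bidirectional=True, dropout=0.6))
    specs.append(_gru_stack("conv_bigru_2x16_dense8_dp06_l1l2", 2, 16, 8,
                            conv=True, bidirectional=True, dropout=0.6, l1l2=3e-5))
    return {s.name: s for s in specs}


def get_architecture(name: str) -> ArchitectureSpec:
    cat = catalog()
    if name not in cat:
        raise KeyError(f"unknown architecture {name!r}; known: {sorted(cat)}")
    return cat[name]


class SequenceClassifier:
    """A built, trainable classifier over encoded ``(N, L, 10)`` tensors.

    ``predict_proba`` runs in eval mode (dropout off) and is deterministic
    for fixed parameters; training-mode forward/backward are driven by the
    training loop.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int,
                 input_length: int | None = None):
        self.spec = spec
        self.seed = seed
        self.input_length = input_length
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        size = N_CHANNELS          # current channel/feature width
        kinds = [l.kind for l in spec.layers]
        for i, ls in enumerate(spec.layers):
            if ls.kind == "conv1d":
                layers.append(nn.Conv1D(size, ls.size, ls.kernel, rng,
                                        l1=ls.l1, l2=ls.l2, name=f"conv{i}"))
                size = ls.size
            elif ls.kind == "maxpool1d":
                layers.append(nn.MaxPool1D(ls.pool))
            elif ls.kind == "gru":
                if ls.dropout_rate:
                    layers.append(nn.Dropout(ls.dropout_rate))
                # the last GRU emits its final hidden state; earlier ones
                # pass the full hidden sequence on
                later = kinds[i + 1:]
                return_sequences = any(k in ("gru", "conv1d", "maxpool1d")
                                       for k in later)
                g = nn.GRU(size, ls.size, rng, bidirectional=ls.bidirectional,
                           return_sequences=return_sequences,
                           l1=ls.l1, l2=ls.l2, name=f"gru{i}")
                layers.append(g)
                size = g.output_size
            elif ls.kind == "dense":
                if ls.dropout_rate:
                    layers.append(nn.Dropout(ls.dropout_rate))
                layers.append(nn.Dense(size, ls.size, rng, activation="relu",
                                       l1=ls.l1, l2=ls.l2, name=f"dense{i}"))
                size = ls.size
            elif ls.kind == "dropout":
                layers.append(nn.Dropout(ls.dropout_rate))
        layers.append(nn.Dense(size, 1, rng, activation=None, name="out"))
        self.layers = layers

    # -- training-mode plumbing -------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = X
        for layer in self.layers:
            h = layer.forward(h, train=train, rng=rng)
        return h[:, 0]                       # logits, shape (N,)

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- inference --------------------------------------------------------
    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        from scipy.special import expit
        if X.ndim != 3 or X.shape[2] != N_CHANNELS:
            raise ValueError(f"expected (N, L, {N_CHANNELS}) input, got {X.shape}")
        if self.input_length is not None and X.shape[1] != self.input_length:
            raise ValueError(
                f"model was trained on {self.input_length}-bp sequences and "
                f"cannot score {X.shape[1]}-bp sequences; retrain at the "
                f"target length")
        chunks = [expit(self.forward(X[i:i + batch_size]))
                  for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(chunks) if chunks else np.empty(0)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    # -- parameter state / persistence ------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        if len(state) != len(ps):
            raise ValueError("state does not match architecture")
        for p, v in zip(ps, state):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value[...] = v

    def save(self, path: str | Path) -> None:
        meta = {"spec": self.spec.to_dict(), "seed": self.seed,
                "input_length": self.input_length}
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SequenceClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(ArchitectureSpec.from_dict(meta["spec"]),
                        seed=meta["seed"], input_length=meta["input_length"])
            n = len(model.params())
            model.set_state([data[f"param_{i}"] for i in range(n)])
        return model


def build_model(spec: ArchitectureSpec | str, seed: int,
                input_length: int | None = None) -> SequenceClassifier:
    """Instantiate a classifier with seed-deterministic initial parameters."""
    if isinstance(spec, str):
        spec = get_architecture(spec)
    return SequenceClassifier(spec, seed=seed, input_length=input_length)
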