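"""Sequence ingestion and feature encoding.

Each DNA sequence of length ``L`` over {A,C,G,T} is encoded as an ``(L, 10)``
matrix: columns 0-3 hold the one-hot base identity (channel order A,C,G,T)
and columns 4-9 hold six normalized dinucleotide physicochemical properties
(Rise, Roll, Shift, Slide, Tilt, Twist) of the base step starting at that
position.  The final position has no following base, so its six property
channels are padded with -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Property column names, in matrix column order 4..9.
PROPERTY_NAMES = ("Rise", "Roll", "Shift", "Slide", "Tilt", "Twist")

#: Normalized dinucleotide physicochemical properties, one 6-vector per
#: ordered dinucleotide.  Values are unitless, min-max normalized to [0, 1].
#: The table is reverse-complement symmetric: each base step and its
#: reverse complement describe the same physical stacking geometry.
DPCP_TABLE: dict[str, tuple[float, ...]] = {
    #       Rise      Roll      Shift     Slide     Tilt  Twist
    "AA": (0.430303, 0.403042, 1.000000, 0.545455, 0.4, 0.833333),
    "AC": (0.818182, 0.695817, 0.618557, 1.000000, 0.7, 0.833333),
    "AG": (0.257576, 0.315589, 0.762887, 0.772727, 0.3, 0.791667),
    "AT": (0.860606, 1.000000, 0.319588, 0.863636, 0.6, 0.750000),
    "CA": (0.045455, 0.220532, 0.360825, 0.090909, 0.1, 0.291667),
    "CC": (0.548485, 0.171103, 0.731959, 0.545455, 0.3, 1.000000),
    "CG": (0.000000, 0.304183, 0.371134, 0.000000, 0.0, 0.333333),
    "CT": (0.257576, 0.315589, 0.762887, 0.772727, 0.3, 0.791667),
    "GA": (0.706061, 0.277567, 0.618557, 0.500000, 0.4, 0.833333),
    "GC": (1.000000, 0.536122, 0.494845, 0.500000, 1.0, 0.750000),
    "GG": (0.548485, 0.171103, 0.731959, 0.545455, 0.3, 1.000000),
    "GT": (0.818182, 0.695817, 0.618557, 1.000000, 0.7, 0.833333),
    "TA": (0.000000, 0.000000, 0.000000, 0.136364, 0.0, 0.000000),
    "TC": (0.706061, 0.277567, 0.618557, 0.500000, 0.4, 0.833333),
    "TG": (0.045455, 0.220532, 0.360825, 0.090909, 0.1, 0.291667),
    "TT": (0.430303, 0.403042, 1.000000, 0.545455, 0.4, 0.833333),
}

PAD_VALUE = -1.0
N_CHANNELS = 10


class EncodingError(ValueError):
    """Raised for sequences that cannot be encoded under the active policy."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA sequence, upper-cased on construction.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : str
        Sequence over {A,C,G,T}; lower case accepted and folded.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise EncodingError(f"sequence {self.id!r} is empty")
        for pos, base in enumerate(self.residues):
            if base not in _BASE_INDEX:
                raise EncodingError(
                    f"sequence {self.id!r}: invalid base {base!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def one_hot(base: str) -> np.ndarray:
    """One-hot encode a single base under the fixed channel order A,C,G,T."""
    try:
        idx = _BASE_INDEX[base.upper()]
    except (KeyError, AttributeError):
        raise EncodingError(f"invalid base {base!r}") from None
    vec = np.zeros(4)
    vec[idx] = 1.0
    return vec


def dpcp_lookup(dinucleotide: str) -> np.ndarray:
    """Six normalized physicochemical properties of an ordered dinucleotide.

    Returns (Rise, Roll, Shift, Slide, Tilt, Twist).
    """
    try:
        values = DPCP_TABLE[dinucleotide.upper()]
    except (KeyError, AttributeError):
        raise EncodingError(f"invalid dinucleotide {dinucleotide!r}") from None
    return np.asarray(values)


def encode_sequence(seq: NucleotideSequence | str) -> np.ndarray:
    """Encode one sequence to its ``(L, 10)`` feature matrix.

    Row ``i`` concatenates the one-hot vector of base ``i`` with the property
    vector of the dinucleotide starting at ``i``; the final row's property
    channels are ``PAD_VALUE`` since no dinucleotide starts there.
    """
    if isinstance(seq, str):
        seq = NucleotideSequence(id="<anonymous>", residues=seq)
    residues = seq.residues
    L = len(residues)
    if L < 2:
        raise EncodingError(f"sequence {seq.id!r}: length {L} < 2 cannot be encoded")
    mat = np.empty((L, N_CHANNELS))
    base_idx = np.fromiter((_BASE_INDEX[b] for b in residues), dtype=np.intp, count=L)
    mat[:, :4] = np.eye(4)[base_idx]
    for i in range(L - 1):
        mat[i, 4:] = DPCP_TABLE[residues[i : i + 2]]
    mat[L - 1, 4:] = PAD_VALUE
    return mat


def decode_one_hot(matrix: np.ndarray) -> str:
    """Recover the residue string from the one-hot channels of an encoding."""
    return "".join(ALPHABET[i] for i in np.argmax(matrix[:, :4], axis=1))


def read_fasta(
    path: str | Path, ambiguity_policy: str = "reject"
) -> list[NucleotideSequence]:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Parameters
    ----------
    ambiguity_policy : {"reject", "drop-sequence"}
        ``reject`` raises on any base outside {A,C,G,T}; ``drop-sequence``
        silently skips records containing such bases.
    """
    if ambiguity_policy not in ("reject", "drop-sequence"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    records: list[NucleotideSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(NucleotideSequence(id=rec.id, residues=str(rec.seq)))
        except EncodingError:
            if ambiguity_policy == "reject":
                raise
    return records


def write_fasta(path: str | Path, seqs: Iterable[NucleotideSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i : i + 70] + "\n")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of (sequence id, label in {0,1})."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>0|1', got {line!r}")
            labels[parts[0]] = int(parts[1])
    return labels


def write_label_table(path: str | Path, ids: Sequence[str], labels: Sequence[int]) -> None:
    with open(path, "w") as fh:
        for sid, lab in zip(ids, labels):
            fh.write(f"{sid}\t{int(lab)}\n")


def encode_dataset(
    seqs: Sequence[NucleotideSequence | str],
    labels: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a same-length collection into an ``(N, L, 10)`` tensor.

    Label order follows sequence order.  Ragged lengths are rejected: the
    classifiers operate at a single fixed length per run.
    """
    if labels is not None and len(labels) != len(seqs):
        raise ValueError(
            f"{len(seqs)} sequences but {len(labels)} labels"
        )
    if len(seqs) == 0:
        return np.empty((0, 0, N_CHANNELS)), np.empty((0,), dtype=int)
    encoded = [encode_sequence(s) for s in seqs]
    lengths = {e.shape[0] for e in encoded}
    if len(lengths) > 1:
        raise EncodingError(
            f"ragged sequence lengths {sorted(lengths)}; a run uses one fixed length"
        )
    X = np.stack(encoded)
    if labels is None:
        y = np.empty((0,), dtype=int)
    else:
        y = np.asarray(labels, dtype=int)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return X, y
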