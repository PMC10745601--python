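"""Numeric sequence representations: label, one-hot, physico-chemical and
profile features, with fixed-length zero padding.

Residues use the 20-symbol one-letter vocabulary; drug atoms use a 27-symbol
element vocabulary.  Unknown symbols (e.g. the 'X' residue) encode as code 0
/ all-zero rows, which keeps the feature dimension fixed at the vocabulary
size as the downstream convolutional encoders require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Vocabulary",
    "EncodedSequence",
    "PropertyTable",
    "RESIDUE_SYMBOLS",
    "ATOM_SYMBOLS",
    "TARGET_FIXED_LENGTH",
    "POCKET_FIXED_LENGTH",
    "residue_vocabulary",
    "atom_vocabulary",
    "label_encode",
    "one_hot_encode",
    "physchem_encode",
    "pad_or_truncate",
    "load_property_table",
]

# Alphabetical one-letter codes of the 20 standard amino acids.
RESIDUE_SYMBOLS = tuple("ACDEFGHIKLMNPQRSTVWY")

# 27-symbol drug-atom vocabulary (common organic elements first, then halogens,
# metalloids and metals seen in ligand files, plus a catch-all).
ATOM_SYMBOLS = (
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se", "As",
    "H", "Li", "Na", "K", "Mg", "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Sr", "UNK",
)

# Fixed sequence lengths: targets are capped at 2100 residues, pockets at 125.
TARGET_FIXED_LENGTH = 2100
POCKET_FIXED_LENGTH = 125


class EncoderConfigError(Exception):
    """A vocabulary or property table is inconsistent."""


@dataclass(frozen=True)
class Vocabulary:
    """An ordered set of encodable symbols."""

    symbols: tuple

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise EncoderConfigError("vocabulary contains duplicate symbols")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        """0-based index, or -1 for unknown symbols."""
        return self._index.get(symbol, -1)

    def __contains__(self, symbol):
        return symbol in self._index

    def __len__(self):
        return len(self.symbols)


def residue_vocabulary() -> Vocabulary:
    return Vocabulary(RESIDUE_SYMBOLS)


def atom_vocabulary() -> Vocabulary:
    return Vocabulary(ATOM_SYMBOLS)


@dataclass
class EncodedSequence:
    """A fixed-length feature matrix with the true (unpadded) length.

    Rows at positions >= ``true_length`` are all zero; ``mask`` is True for
    exactly the first ``true_length`` rows.  ``truncated`` records whether
    the input exceeded the fixed length.
    """

    matrix: np.ndarray
    true_length: int
    mask: np.ndarray
    truncated: bool = False

    @property
    def valid(self) -> np.ndarray:
        """The first ``true_length`` rows (the encoded sequence itself)."""
        return self.matrix[: self.true_length]


def label_encode(sequence, vocab: Vocabulary) -> np.ndarray:
    """Integer codes: 1-based vocabulary index; unknown symbols code as 0."""
    return np.array([vocab.index(s) + 1 for s in sequence], dtype=np.int64)


def one_hot_encode(sequence, vocab: Vocabulary) -> np.ndarray:
    """L x |vocab| indicator matrix; unknown symbols yield all-zero rows."""
    out = np.zeros((len(sequence), vocab.size), dtype=float)
    for i, s in enumerate(sequence):
        j = vocab.index(s)
        if j >= 0:
            out[i, j] = 1.0
    return out


@dataclass
class PropertyTable:
    """Per-symbol real-valued descriptors (24-dim for residues, 9-dim for
    atoms by default), with a provenance note per column."""

    mapping: dict
    columns: list = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(v) for v in self.mapping.values()}
        if len(lengths) > 1:
            raise EncoderConfigError(
                f"property vectors have inconsistent lengths: {sorted(lengths)}"
            )

    @property
    def dim(self) -> int:
        return len(next(iter(self.mapping.values())))

    def validate_vocabulary(self, vocab: Vocabulary) -> None:
        missing = [s for s in vocab.symbols if s not in self.mapping]
        if missing:
            raise EncoderConfigError(f"property table missing symbols: {missing}")

    def standardized(self) -> dict:
        """Column-wise zero-mean / unit-variance version, computed over the
        table's own entries (deterministic).  Zero-variance columns are only
        centered."""
        keys = sorted(self.mapping)
        arr = np.array([self.mapping[k] for k in keys], dtype=float)
        mean = arr.mean(axis=0)
        std = arr.std(axis=0)
        std[std == 0.0] = 1.0
        return {k: (np.asarray(self.mapping[k], float) - mean) / std for k in keys}


def load_property_table(which_or_path) -> PropertyTable:
    """Load a property table from a YAML file.

    ``which_or_path`` may be "residues"/"atoms" for the shipped default
    tables, or a path to a user-supplied YAML file with the same layout
    (``columns`` plus ``values: {symbol: [..]}``).
    """
    if which_or_path in ("residues", "atoms"):
        name = (
            "residue_properties.yaml"
            if which_or_path == "residues"
            else "atom_properties.yaml"
        )
        text = resources.files("heterodta.data").joinpath(name).read_text()
    else:
        text = Path(which_or_path).read_text()
    payload = yaml.safe_load(text)
    return PropertyTable(
        mapping={str(k): list(map(float, v)) for k, v in payload["values"].items()},
        columns=list(payload.get("columns", [])),
    )


def physchem_encode(sequence, table: PropertyTable, vocab: Vocabulary | None = None) -> np.ndarray:
    """L x d matrix of standardized physico-chemical descriptors.

    Columns are standardized to zero mean / unit variance over the table's
    entries; unknown symbols yield all-zero rows.
    """
    if vocab is not None:
        table.validate_vocabulary(vocab)
    std_map = table.standardized()
    d = table.dim
    out = np.zeros((len(sequence), d), dtype=float)
    for i, s in enumerate(sequence):
        vec = std_map.get(s)
        if vec is not None:
            out[i] = vec
    return out


def pad_or_truncate(matrix: np.ndarray, fixed_length: int) -> EncodedSequence:
    """Zero-pad (or truncate) an L x d feature matrix to ``fixed_length`` rows."""
    if fixed_length < 1:
        raise ValueError("fixed_length must be >= 1")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected an L x d matrix")
    length, d = matrix.shape
    true_length = min(length, fixed_length)
    out = np.zeros((fixed_length, d), dtype=matrix.dtype)
    out[:true_length] = matrix[:true_length]
    mask = np.zeros(fixed_length, dtype=bool)
    mask[:true_length] = True
    return EncodedSequence(
        matrix=out,
        true_length=true_length,
        mask=mask,
        truncated=length > fixed_length,
    )
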