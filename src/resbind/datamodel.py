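"""Core domain types: proteins, label tracks, splits, run configuration.

Positions are 0-based everywhere inside the package; the 1-based
convention of the on-disk formats is applied only at IO boundaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "LabelTrack",
    "DatasetSplit",
    "RunConfig",
    "PredictionRow",
    "PredictionTable",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_LETTERS = set(AMINO_ACIDS) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence, the unit of all IO."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id {self.id!r} must be non-empty without whitespace")
        seq = self.sequence.upper()
        seq = "".join(c if c in _VALID_LETTERS else "X" for c in seq)
        if len(seq) == 0:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabelTrack:
    """Per-residue binary binding labels with a validity mask.

    ``mask[i] == 0`` marks residues whose annotation is undefined; such
    residues are excluded from training losses and from every metric.
    """

    protein_id: str
    labels: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.labels.shape != self.mask.shape or self.labels.ndim != 1:
            raise ValueError("labels and mask must be 1-D arrays of equal length")
        if not np.isin(self.labels, (0, 1)).all() or not np.isin(self.mask, (0, 1)).all():
            raise ValueError("labels and mask entries must be 0 or 1")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_effective(self) -> int:
        """Number of residues with a defined label (N in the loss)."""
        return int(self.mask.sum())

    @property
    def n_positive(self) -> int:
        return int((self.labels * self.mask).sum())


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test id sets, reproducible from a seed."""

    train_ids: tuple
    valid_ids: tuple
    test_ids: tuple = ()
    seed: int = 0

    def __post_init__(self):
        parts = [set(self.train_ids), set(self.valid_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split parts must be pairwise disjoint")


# numeric fields and their types, used for config validation
_INT_KEYS = {
    "d_hid", "n_enc_layers", "n_dec_layers", "n_heads", "d_ff",
    "kernel_size", "batch_size", "window_size", "seed",
}
_FLOAT_KEYS = {"weight_decay", "learning_rate", "dropout_rate", "decision_threshold", "loss_weight"}


@dataclass
class RunConfig:
    """Architecture and optimisation hyperparameters.

    ``loss_weight=None`` means "use the non-binding/binding residue ratio
    of the training split", the natural re-balancing default.
    """

    d_hid: int = 128
    n_enc_layers: int = 3
    n_dec_layers: int = 3
    n_heads: int = 8
    d_ff: int = 256
    kernel_size: int = 7
    weight_decay: float = 1e-4
    batch_size: int = 128
    learning_rate: float = 3e-3
    dropout_rate: float = 0.1
    loss_weight: float | None = None
    window_size: int = 15
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.d_hid % self.n_heads != 0:
            raise ValueError(f"d_hid={self.d_hid} must be divisible by n_heads={self.n_heads}")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie strictly between 0 and 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.loss_weight is not None and self.loss_weight <= 0:
            raise ValueError("loss_weight must be positive")

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        unknown = set(values) - cls.field_names()
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for key, val in values.items():
            if key == "loss_weight" and val is None:
                coerced[key] = None
                continue
            if isinstance(val, bool) or not isinstance(val, (int, float)):
                raise ValueError(f"config key {key!r} must be numeric, got {val!r}")
            coerced[key] = int(val) if key in _INT_KEYS else float(val)
        return cls(**coerced)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PredictionRow:
    protein_id: str
    position: int  # 0-based internally
    residue: str
    probability: float
    call: int


class PredictionTable:
    """Per-residue binding probabilities and hard calls for one or more proteins."""

    def __init__(self, rows: Sequence[PredictionRow] = ()):
        self.rows: list[PredictionRow] = list(rows)
        for row in self.rows:
            if not 0.0 <= row.probability <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, PredictionTable) and self.rows == other.rows

    def append(self, row: PredictionRow) -> None:
        self.rows.append(row)

    def protein_ids(self) -> list:
        seen: dict = {}
        for row in self.rows:
            seen.setdefault(row.protein_id, None)
        return list(seen)

    def for_protein(self, protein_id: str) -> "PredictionTable":
        return PredictionTable([r for r in self.rows if r.protein_id == protein_id])

    def probabilities(self) -> np.ndarray:
        return np.array([r.probability for r in self.rows], dtype=np.float64)

    def calls(self) -> np.ndarray:
        return np.array([r.call for r in self.rows], dtype=np.int8)
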