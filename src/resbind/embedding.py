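"""Per-residue embedding matrices behind a pluggable adapter interface.

The default embedder is synthetic and fully deterministic: each residue
vector is the sum of a per-letter basis vector, a smoothed local-window
average of neighbouring basis vectors, and protein-specific noise.  It
stands in for a protein language model so the whole pipeline runs with
no downloads; real language-model embeddings plug in through the same
registry without the core ever inspecting provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .datamodel import ProteinRecord

__all__ = [
    "EmbeddingMatrix",
    "PaddedBatch",
    "SyntheticEmbedder",
    "synthetic_embed",
    "pad_batch",
    "register_embedder",
    "get_embedder",
]

DEFAULT_DIM = 2560  # width produced by the large language-model backbone
_CONTEXT_HALF_WIDTH = 3  # residues on each side entering the smoothing term


@dataclass
class EmbeddingMatrix:
    """L x d matrix of per-residue features for one protein."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("embedding values must be a 2-D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError(f"embedding for {self.protein_id!r} contains non-finite entries")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class PaddedBatch:
    """Zero-padded stack of embeddings with a residue-validity mask."""

    values: np.ndarray  # (B, L_max, d)
    mask: np.ndarray  # (B, L_max) in {0,1}; 1 = real residue
    lengths: np.ndarray  # (B,)
    protein_ids: tuple


def _seeded_rng(*key) -> np.random.Generator:
    """Generator keyed by an arbitrary tuple of ints/strings, stable across runs."""
    digest = hashlib.blake2b("\x1f".join(map(str, key)).encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def _letter_basis(seed: int, d_p: int) -> dict:
    from .datamodel import AMINO_ACIDS

    return {
        letter: _seeded_rng(seed, "letter", letter).standard_normal(d_p)
        for letter in AMINO_ACIDS + "X"
    }


def synthetic_embed(
    protein: ProteinRecord,
    d_p: int = 64,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> EmbeddingMatrix:
    """Deterministic synthetic embedding.

    e_i = u(aa_i) + 0.5 * mean(u(aa_j), j in [i-3, i+3] within the
    sequence) + eps_i, where each u(letter) is a unit-variance vector
    keyed by (seed, letter) and eps is keyed by (seed, protein id) with
    standard deviation ``noise_sd``.
    """
    if d_p < 8:
        raise ValueError("d_p must be at least 8")
    basis = _letter_basis(seed, d_p)
    L = len(protein)
    U = np.stack([basis[c] for c in protein.sequence])  # (L, d_p)
    smoothed = np.empty_like(U)
    for i in range(L):
        lo, hi = max(0, i - _CONTEXT_HALF_WIDTH), min(L, i + _CONTEXT_HALF_WIDTH + 1)
        smoothed[i] = U[lo:hi].mean(axis=0)
    values = U + 0.5 * smoothed
    if noise_sd > 0:
        values = values + _seeded_rng(seed, "noise", protein.id).normal(0.0, noise_sd, size=(L, d_p))
    return EmbeddingMatrix(protein.id, values)


class SyntheticEmbedder:
    """Callable adapter wrapping :func:`synthetic_embed` with fixed settings."""

    def __init__(self, d_p: int = 64, seed: int = 0, noise_sd: float = 0.1):
        self.d_p = d_p
        self.seed = seed
        self.noise_sd = noise_sd

    def __call__(self, protein: ProteinRecord) -> EmbeddingMatrix:
        return synthetic_embed(protein, d_p=self.d_p, seed=self.seed, noise_sd=self.noise_sd)


def pad_batch(matrices) -> PaddedBatch:
    """Stack embeddings into a (B, L_max, d) array with zero padding."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("pad_batch requires at least one embedding")
    dims = {m.dim for m in matrices}
    if len(dims) != 1:
        raise ValueError(f"mixed embedding dimensions: {sorted(dims)}")
    lengths = np.array([m.length for m in matrices])
    L_max, d = int(lengths.max()), dims.pop()
    values = np.zeros((len(matrices), L_max, d))
    mask = np.zeros((len(matrices), L_max), dtype=np.int8)
    for b, m in enumerate(matrices):
        values[b, : m.length] = m.values
        mask[b, : m.length] = 1
    return PaddedBatch(values, mask, lengths, tuple(m.protein_id for m in matrices))


# -- adapter registry ---------------------------------------------------

_REGISTRY: dict = {}


def register_embedder(name: str, factory) -> None:
    """Register an embedder factory: ``factory(**kwargs) -> callable(protein)``."""
    _REGISTRY[name] = factory


def get_embedder(name: str, **kwargs):
    """Instantiate a registered embedder and wrap it with contract checks."""
    if name not in _REGISTRY:
        raise KeyError(f"no embedder registered under {name!r}; known: {sorted(_REGISTRY)}")
    inner = _REGISTRY[name](**kwargs)

    def checked(protein: ProteinRecord) -> EmbeddingMatrix:
        matrix = inner(protein)
        if not isinstance(matrix, EmbeddingMatrix):
            raise TypeError("embedder must return an EmbeddingMatrix")
        if matrix.length != len(protein):
            raise ValueError(
                f"embedder returned {matrix.length} rows for protein {protein.id!r} "
                f"of length {len(protein)}"
            )
        return matrix

    return checked


register_embedder("synthetic", SyntheticEmbedder)
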