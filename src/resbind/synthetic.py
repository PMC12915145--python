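"""Benchmark-shaped synthetic datasets with a planted local-window rule.

Proteins are i.i.d. random sequences; labels come from thresholding the
projection of window-averaged synthetic embeddings onto a hidden unit
direction, with a small label-flip noise.  The resulting datasets have
the two features that make binding-site prediction hard in practice —
a local signal in the embeddings and strong class imbalance — while
staying fully regenerable from (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import AMINO_ACIDS, LabelTrack, ProteinRecord
from .embedding import EmbeddingMatrix, SyntheticEmbedder, _seeded_rng

__all__ = [
    "PlantedRuleSpec",
    "SyntheticDataset",
    "generate_proteins",
    "window_scores",
    "plant_labels",
    "calibrate_intercept",
    "make_benchmark",
    "dataset_from_manifest",
]


@dataclass
class PlantedRuleSpec:
    """A linear rule on window-averaged embeddings.

    label_i = 1 iff v . mean(e_{i-h..i+h}) >= b, then flipped with
    probability rho.  The direction v is drawn once from the seed; the
    intercept b is calibrated so the positive fraction is about pi.
    """

    d_p: int = 64
    half_width: int = 2
    positive_fraction: float = 0.12
    flip_probability: float = 0.02
    seed: int = 0
    direction: np.ndarray | None = field(default=None, repr=False)
    intercept: float | None = None

    def __post_init__(self):
        if not 0.0 < self.positive_fraction < 0.5:
            raise ValueError("positive_fraction must lie in (0, 0.5)")
        if not 0.0 <= self.flip_probability < 0.5:
            raise ValueError("flip_probability must lie in [0, 0.5)")
        if self.direction is None:
            v = _seeded_rng(self.seed, "rule-direction").standard_normal(self.d_p)
            self.direction = v / np.linalg.norm(v)
        else:
            self.direction = np.asarray(self.direction, dtype=np.float64)
            if not np.isclose(np.linalg.norm(self.direction), 1.0):
                raise ValueError("direction must have unit norm")


@dataclass
class SyntheticDataset:
    proteins: list
    embeddings: dict
    tracks: dict
    rule: PlantedRuleSpec
    seed: int

    @property
    def positive_fraction(self) -> float:
        pos = sum(t.n_positive for t in self.tracks.values())
        n = sum(t.n_effective for t in self.tracks.values())
        return pos / n if n else float("nan")

    def ids(self) -> list:
        return [p.id for p in self.proteins]


def generate_proteins(n: int, length_range: tuple, seed: int,
                      id_prefix: str = "syn") -> list:
    """n i.i.d. uniform-composition proteins with uniform lengths."""
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n)))
    proteins = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        proteins.append(ProteinRecord(f"{id_prefix}{i:0{width}d}", seq))
    return proteins


def window_scores(embedding: EmbeddingMatrix, rule: PlantedRuleSpec) -> np.ndarray:
    """score_i = v . mean(e_{i-h..i+h}), window truncated at the ends."""
    if embedding.dim != rule.d_p:
        raise ValueError(f"embedding width {embedding.dim} != rule d_p {rule.d_p}")
    proj = embedding.values @ rule.direction  # (L,)
    L, h = embedding.length, rule.half_width
    out = np.empty(L)
    for i in range(L):
        out[i] = proj[max(0, i - h): min(L, i + h + 1)].mean()
    return out


def calibrate_intercept(scores, positive_fraction: float) -> float:
    """The empirical (1 - pi)-quantile of the pooled scores."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 100:
        raise ValueError("need at least 100 scores to calibrate the intercept")
    if not 0.0 < positive_fraction < 1.0:
        raise ValueError("positive_fraction must lie in (0, 1)")
    return float(np.quantile(scores, 1.0 - positive_fraction))


def plant_labels(embedding: EmbeddingMatrix, rule: PlantedRuleSpec) -> LabelTrack:
    """Threshold the rule score, then flip labels with probability rho.

    All residues are masked in: the generator has no undefined labels.
    """
    if rule.intercept is None:
        raise ValueError("rule intercept not calibrated; call calibrate_intercept first")
    labels = (window_scores(embedding, rule) >= rule.intercept).astype(np.int8)
    if rule.flip_probability > 0:
        rng = _seeded_rng(rule.seed, "flip", embedding.protein_id)
        flips = rng.random(labels.size) < rule.flip_probability
        labels = np.where(flips, 1 - labels, labels).astype(np.int8)
    return LabelTrack(embedding.protein_id, labels, np.ones(labels.size, dtype=np.int8))


def _build_split(proteins, embedder, rule, seed) -> SyntheticDataset:
    embeddings = {p.id: embedder(p) for p in proteins}
    tracks = {p.id: plant_labels(embeddings[p.id], rule) for p in proteins}
    return SyntheticDataset(proteins, embeddings, tracks, rule, seed)


def make_benchmark(
    n_train: int = 200,
    n_valid: int = 50,
    n_test: int = 50,
    *,
    length_range: tuple = (50, 150),
    d_p: int = 64,
    positive_fraction: float = 0.12,
    flip_probability: float = 0.02,
    half_width: int = 2,
    embed_noise_sd: float = 0.1,
    seed: int = 0,
):
    """Disjoint train/valid/test datasets sharing one calibrated rule.

    Returns ``(train, valid, test, manifest)``; the manifest is a JSON
    serialisable record sufficient for exact regeneration.
    """
    total = n_train + n_valid + n_test
    proteins = generate_proteins(total, length_range, seed)
    embedder = SyntheticEmbedder(d_p=d_p, seed=seed, noise_sd=embed_noise_sd)
    rule = PlantedRuleSpec(
        d_p=d_p, half_width=half_width, positive_fraction=positive_fraction,
        flip_probability=flip_probability, seed=seed,
    )
    embeddings = {p.id: embedder(p) for p in proteins}
    pooled = np.concatenate([window_scores(embeddings[p.id], rule) for p in proteins])
    rule.intercept = calibrate_intercept(pooled, positive_fraction)

    parts = (proteins[:n_train], proteins[n_train:n_train + n_valid], proteins[n_train + n_valid:])
    datasets = tuple(_build_split(part, embedder, rule, seed) for part in parts)
    manifest = {
        "n_train": n_train, "n_valid": n_valid, "n_test": n_test,
        "length_range": list(length_range), "d_p": d_p,
        "positive_fraction": positive_fraction, "flip_probability": flip_probability,
        "half_width": half_width, "embed_noise_sd": embed_noise_sd, "seed": seed,
        "calibrated_intercept": rule.intercept,
    }
    return (*datasets, manifest)


def dataset_from_manifest(manifest: dict | str | Path):
    """Regenerate the exact benchmark triple recorded in a manifest."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    return make_benchmark(
        manifest["n_train"], manifest["n_valid"], manifest["n_test"],
        length_range=tuple(manifest["length_range"]), d_p=manifest["d_p"],
        positive_fraction=manifest["positive_fraction"],
        flip_probability=manifest["flip_probability"],
        half_width=manifest["half_width"], embed_noise_sd=manifest["embed_noise_sd"],
        seed=manifest["seed"],
    )
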