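"""The full binding-site network and its checkpoint format.

Pipeline per protein: embed -> encode whole sequence (gated conv
encoder) -> for every residue, build a local window from the projected
raw embeddings -> cross-attention decoder against the encoded protein
-> norm-weighted aggregation -> fully connected classifier -> binding
probability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._autodiff import Parameter, Tensor
from .datamodel import PredictionRow, PredictionTable, ProteinRecord, RunConfig
from .decoder import Classifier, DecoderLayer, aggregate_significance, build_local_context
from .embedding import EmbeddingMatrix
from .encoder import Encoder
from .nn import Linear

__all__ = ["BindingSiteModel", "predict_protein", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_FORMAT_VERSION = 1


class BindingSiteModel:
    """Encoder + cross-attention decoder + classifier with all weights."""

    def __init__(self, config: RunConfig, d_p: int, seed: int | None = None,
                 squared_norm_aggregation: bool = False, dtype=np.float64):
        self.config = config
        self.d_p = d_p
        self.squared_norm_aggregation = squared_norm_aggregation
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(config.seed if seed is None else seed)
        self.encoder = Encoder(d_p, config, rng)
        # dedicated projection of the raw embeddings entering the decoder,
        # separate from the encoder's input projection
        self.local_proj = Linear(d_p, config.d_hid, rng)
        self.pos_embed = Parameter(rng.normal(0.0, 0.02, size=(config.window_size, config.d_hid)))
        self.dec_layers = [DecoderLayer(config, rng) for _ in range(config.n_dec_layers)]
        self.classifier = Classifier(config.d_hid, rng)
        if self.dtype != np.float64:  # single precision: standard for training
            for p in self.parameters():
                p.data = p.data.astype(self.dtype)

    # -- parameter plumbing -------------------------------------------
    def parameters(self) -> list:
        params = self.encoder.parameters() + self.local_proj.parameters() + [self.pos_embed]
        for layer in self.dec_layers:
            params += layer.parameters()
        params += self.classifier.parameters()
        return params

    def state_arrays(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.array(a, dtype=self.dtype)

    # -- forward passes ------------------------------------------------
    def encode_protein(self, embedding: EmbeddingMatrix,
                       rng: np.random.Generator | None = None,
                       training: bool = False) -> Tensor:
        P = Tensor(embedding.values[None].astype(self.dtype, copy=False))  # (1, L, d_p)
        mask = np.ones((1, embedding.length))
        return self.encoder(P, mask, rng=rng, training=training)

    def forward_residues(
        self,
        embedding: EmbeddingMatrix,
        positions: np.ndarray,
        H_p: Tensor | None = None,
        rng: np.random.Generator | None = None,
        training: bool = False,
        collect_attention: bool = False,
    ):
        """Probabilities and logits for the given residue positions.

        Returns (prob Tensor (B,), logits Tensor (B, 2), attention list).
        """
        if embedding.dim != self.d_p:
            raise ValueError(f"embedding width {embedding.dim} != model d_p {self.d_p}")
        if H_p is None:
            H_p = self.encode_protein(embedding, rng=rng, training=training)
        L = embedding.length
        values = embedding.values.astype(self.dtype, copy=False)
        P_proj = self.local_proj(Tensor(values))  # (L, d_hid)
        ctx = build_local_context(P_proj, positions, self.config.window_size, self.pos_embed)
        x, pmask = ctx.values, np.ones((1, L))
        attn = []
        for layer in self.dec_layers:
            x, weights = layer(x, H_p, ctx.mask, pmask, rng=rng, training=training)
            if collect_attention:
                attn.append(tuple(w.data for w in weights))
        H_agg = aggregate_significance(x, ctx.mask, squared_norm=self.squared_norm_aggregation)
        z, prob = self.classifier(H_agg)
        return prob, z, attn

    def predict_probabilities(self, embedding: EmbeddingMatrix, chunk_size: int = 256) -> np.ndarray:
        """Deterministic inference over all residues, chunked for memory."""
        H_p = self.encode_protein(embedding)
        out = []
        for start in range(0, embedding.length, chunk_size):
            positions = np.arange(start, min(start + chunk_size, embedding.length))
            prob, _, _ = self.forward_residues(embedding, positions, H_p=H_p)
            out.append(prob.data)
        return np.concatenate(out)


def predict_protein(
    protein: ProteinRecord,
    embedder,
    model: BindingSiteModel,
    chunk_size: int = 256,
) -> PredictionTable:
    """One probability and hard call per residue of ``protein``."""
    embedding = embedder(protein)
    if embedding.length != len(protein):
        raise ValueError("embedding length does not match the protein sequence")
    probs = model.predict_probabilities(embedding, chunk_size=chunk_size)
    threshold = model.config.decision_threshold
    rows = [
        PredictionRow(protein.id, i, protein.sequence[i], float(p), int(p >= threshold))
        for i, p in enumerate(probs)
    ]
    return PredictionTable(rows)


def save_checkpoint(model: BindingSiteModel, path: str | Path) -> None:
    """Single-file checkpoint embedding the run configuration and a version tag."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "d_p": model.d_p,
        "squared_norm_aggregation": model.squared_norm_aggregation,
        "dtype": model.dtype.name,
        "config": model.config.to_dict(),
    }
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> BindingSiteModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
        config = RunConfig.from_dict({k: v for k, v in meta["config"].items() if v is not None})
        model = BindingSiteModel(config, d_p=meta["d_p"],
                                 squared_norm_aggregation=meta["squared_norm_aggregation"],
                                 dtype=np.dtype(meta.get("dtype", "float64")))
        arrays = [data[k] for k in sorted(k for k in data.files if k.startswith("param_"))]
    model.load_state_arrays(arrays)
    return model
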