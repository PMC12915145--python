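"""Cross-attention decoder over per-residue local windows, significance
weighted aggregation, and the final classifier.

Each target residue contributes a window of ``window_size`` residues
centred on itself (built from the original embeddings after a dedicated
projection, plus a learned within-window position embedding).  The
window self-attends, cross-attends to the encoded whole protein, and
passes through a position-wise feed-forward net; each sublayer is
wrapped in residual + layer norm.  No causal mask is used anywhere —
only the validity masks for window overhang and batch padding.

The window features are then collapsed to a single vector per residue
by softmax weights over the feature norms, and classified by a small
fully connected stack into binding / non-binding logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, as_tensor
from .datamodel import RunConfig
from .nn import FeedForward, LayerNorm, MultiHeadAttention, dropout, masked_softmax

__all__ = [
    "LocalContext",
    "attention",
    "build_local_context",
    "DecoderLayer",
    "aggregate_significance",
    "Classifier",
]


@dataclass
class LocalContext:
    """Windows of projected residue features for a batch of target residues."""

    values: Tensor  # (B, L_l, d_hid)
    mask: np.ndarray  # (B, L_l); 0 where the window overhangs a sequence end
    center_index: int


def attention(Q, K, V, key_mask=None):
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_k)) V.

    Masked keys are excluded before the softmax and receive exactly zero
    weight.  Returns ``(output, weights)``.
    """
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    d_k = Q.shape[-1]
    if K.shape[-1] != d_k:
        raise ValueError("query and key widths differ")
    if key_mask is None:
        key_mask = np.ones(K.shape[:-1])
    key_mask = np.asarray(key_mask, dtype=K.data.dtype)
    if key_mask.shape[-1] != K.shape[-2]:
        raise ValueError("key_mask must align with the key rows")
    if np.any(key_mask.sum(axis=-1) == 0):
        raise ValueError("every query needs at least one unmasked key")
    scores = (Q @ K.swapaxes(-1, -2)) / np.sqrt(d_k)
    weights = masked_softmax(scores, key_mask[..., None, :] if key_mask.ndim == K.ndim - 1 else key_mask)
    return weights @ V, weights


def build_local_context(
    P_projected: Tensor,
    positions: np.ndarray,
    window_size: int,
    position_embedding: Tensor | None = None,
) -> LocalContext:
    """Gather the window of ``window_size`` residues centred on each position.

    Out-of-range slots are zero with mask 0; the learned within-window
    position embedding is added to valid slots only.
    """
    if window_size % 2 == 0:
        raise ValueError("window_size must be odd")
    P_projected = as_tensor(P_projected)
    L = P_projected.shape[0]
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size and (positions.min() < 0 or positions.max() >= L):
        raise ValueError("positions out of range")
    half = (window_size - 1) // 2
    offsets = np.arange(-half, half + 1)
    idx = positions[:, None] + offsets[None, :]  # (B, L_l)
    valid = ((idx >= 0) & (idx < L)).astype(P_projected.data.dtype)
    clipped = np.clip(idx, 0, L - 1)
    windows = P_projected[clipped] * valid[..., None]
    if position_embedding is not None:
        if position_embedding.shape != (window_size, P_projected.shape[-1]):
            raise ValueError("position embedding shape must be (window_size, d_hid)")
        windows = windows + position_embedding * valid[..., None]
    return LocalContext(values=windows, mask=valid, center_index=half)


class DecoderLayer:
    """Self-attention -> cross-attention -> feed-forward, each with
    residual + layer norm; padded window slots are re-zeroed at the end."""

    def __init__(self, config: RunConfig, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(config.d_hid, config.n_heads, rng)
        self.cross_attn = MultiHeadAttention(config.d_hid, config.n_heads, rng)
        self.ffn = FeedForward(config.d_hid, config.d_ff, rng)
        self.norm1 = LayerNorm(config.d_hid)
        self.norm2 = LayerNorm(config.d_hid)
        self.norm3 = LayerNorm(config.d_hid)
        self.dropout_rate = config.dropout_rate

    def __call__(
        self,
        x: Tensor,  # (B, L_l, d_hid)
        H_p: Tensor,  # (1, L_p, d_hid) encoded protein, shared across the batch
        window_mask: np.ndarray,  # (B, L_l)
        protein_mask: np.ndarray,  # (1, L_p) or (L_p,)
        rng: np.random.Generator | None = None,
        training: bool = False,
    ):
        """Returns (x', (self_weights, cross_weights))."""
        wmask = np.asarray(window_mask, dtype=x.data.dtype)
        pmask = np.atleast_2d(np.asarray(protein_mask, dtype=x.data.dtype))
        sa, w_self = self.self_attn(x, x, x, wmask)
        x = self.norm1(x + dropout(sa, self.dropout_rate, rng, training))
        ca, w_cross = self.cross_attn(x, H_p, H_p, pmask)
        x = self.norm2(x + dropout(ca, self.dropout_rate, rng, training))
        ff = self.ffn(x)
        x = self.norm3(x + dropout(ff, self.dropout_rate, rng, training))
        return x * wmask[..., None], (w_self, w_cross)

    def parameters(self):
        params = self.self_attn.parameters() + self.cross_attn.parameters() + self.ffn.parameters()
        params += self.norm1.parameters() + self.norm2.parameters() + self.norm3.parameters()
        return params


def aggregate_significance(
    H_window: Tensor,
    window_mask: np.ndarray,
    squared_norm: bool = False,
) -> Tensor:
    """Collapse (B, L_l, d) windows to (B, d) by norm-softmax weights.

    weight_j = exp(||H_j||) / sum_k exp(||H_k||) over valid rows only,
    stabilised by subtracting the per-window maximum norm.  With
    ``squared_norm`` the exponent is ||H_j||^2 instead.
    """
    H_window = as_tensor(H_window)
    mask = np.asarray(window_mask, dtype=H_window.data.dtype)
    if np.any(mask.sum(axis=-1) == 0):
        raise ValueError("each window needs at least one valid row")
    sq = (H_window * H_window).sum(axis=-1)  # (B, L_l)
    norms = sq if squared_norm else (sq + 1e-12).sqrt()
    weights = masked_softmax(norms, mask)
    return (weights[..., None] * H_window).sum(axis=-2)


class Classifier:
    """Three fully connected layers with ReLU between: d_hid -> 64 -> 32 -> 2."""

    HIDDEN = (64, 32)

    def __init__(self, d_hid: int, rng: np.random.Generator):
        from .nn import Linear

        h1, h2 = self.HIDDEN
        self.fc1 = Linear(d_hid, h1, rng)
        self.fc2 = Linear(h1, h2, rng)
        self.fc3 = Linear(h2, 2, rng)

    def __call__(self, H_agg: Tensor):
        """Returns (logits z of shape (B, 2), probability of class 1)."""
        z = self.fc3(self.fc2(self.fc1(H_agg).relu()).relu())
        # softmax over two classes; column 1 is the binding probability
        m = z.data.max(axis=-1, keepdims=True)
        e = (z - m).exp()
        prob = e[..., 1] / e.sum(axis=-1)
        return z, prob

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters() + self.fc3.parameters()
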