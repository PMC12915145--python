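"""Gated convolutional protein feature encoder.

The encoder projects per-residue input features to a hidden width, then
applies a stack of same-length 1-D convolution blocks.  Each block
doubles the channel count, gates it through a GLU, adds the block input
and rescales the sum by sqrt(0.5) so activation variance is preserved
through depth, and re-zeroes padded positions so no information bleeds
in from padding.  A single layer normalisation is applied to the final
output.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, as_tensor
from .datamodel import RunConfig
from .nn import Conv1d, LayerNorm, Linear, dropout

__all__ = ["glu", "ConvGLUBlock", "Encoder", "RESIDUAL_SCALE"]

RESIDUAL_SCALE = float(np.sqrt(0.5))


def glu(x: Tensor) -> Tensor:
    """Gated linear unit: split the trailing axis in half, a * sigmoid(b)."""
    x = as_tensor(x)
    d2 = x.shape[-1]
    if d2 % 2 != 0:
        raise ValueError(f"GLU input width must be even, got {d2}")
    d = d2 // 2
    lead = (slice(None),) * (x.ndim - 1)
    a = x[lead + (slice(0, d),)]
    b = x[lead + (slice(d, d2),)]
    return a * b.sigmoid()


class ConvGLUBlock:
    """One convolution + GLU block with a scaled residual connection."""

    def __init__(self, d_hid: int, kernel_size: int, rng: np.random.Generator):
        self.conv = Conv1d(d_hid, 2 * d_hid, kernel_size, rng)
        self.d_hid = d_hid

    def __call__(
        self,
        H: Tensor,
        mask: np.ndarray,
        dropout_rate: float = 0.0,
        rng: np.random.Generator | None = None,
        training: bool = False,
    ) -> Tensor:
        if H.shape[-1] != self.d_hid:
            raise ValueError(f"expected {self.d_hid} channels, got {H.shape[-1]}")
        gated = glu(self.conv(H))
        gated = dropout(gated, dropout_rate, rng, training)
        out = (H + gated) * RESIDUAL_SCALE
        # padded positions are zeroed after every block
        return out * np.asarray(mask, dtype=out.data.dtype)[..., None]

    def parameters(self):
        return self.conv.parameters()


class Encoder:
    """Input projection -> n conv/GLU blocks -> final layer norm."""

    def __init__(self, d_p: int, config: RunConfig, rng: np.random.Generator):
        self.config = config
        self.in_proj = Linear(d_p, config.d_hid, rng)
        self.blocks = [
            ConvGLUBlock(config.d_hid, config.kernel_size, rng)
            for _ in range(config.n_enc_layers)
        ]
        self.norm = LayerNorm(config.d_hid)

    def __call__(
        self,
        P: Tensor | np.ndarray,
        mask: np.ndarray,
        rng: np.random.Generator | None = None,
        training: bool = False,
    ) -> Tensor:
        """Encode a padded batch (B, L, d_p) -> (B, L, d_hid)."""
        P = as_tensor(P)
        mask = np.asarray(mask, dtype=P.data.dtype)
        H = self.in_proj(P) * mask[..., None]
        for block in self.blocks:
            H = block(H, mask, self.config.dropout_rate, rng, training)
        return self.norm(H) * mask[..., None]

    def parameters(self):
        params = self.in_proj.parameters() + self.norm.parameters()
        for block in self.blocks:
            params += block.parameters()
        return params
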