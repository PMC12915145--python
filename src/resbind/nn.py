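"""Neural-network layers built on the internal autodiff core.

Layers hold :class:`~resbind._autodiff.Parameter` leaves and expose a
``__call__`` producing graph tensors.  Initialisation is driven by an
explicit ``numpy.random.Generator`` so that model construction is a pure
function of the seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Parameter, Tensor, pad_axis

__all__ = [
    "Linear",
    "LayerNorm",
    "Conv1d",
    "MultiHeadAttention",
    "FeedForward",
    "softmax",
    "masked_softmax",
    "scaled_dot_attention",
    "dropout",
]

_NEG_BIG = 1e30  # additive mask value; exp(-1e30 - m) underflows to exactly 0


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-subtraction with a detached constant: value and gradient unchanged
    m = x.data.max(axis=axis, keepdims=True)
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax(scores: Tensor, key_mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax where positions with ``key_mask == 0`` receive exactly 0 weight."""
    key_mask = np.asarray(key_mask, dtype=scores.data.dtype)
    shift = (1.0 - key_mask) * _NEG_BIG
    masked = scores - shift
    m = masked.data.max(axis=axis, keepdims=True)
    e = (masked - m).exp() * key_mask
    return e / e.sum(axis=axis, keepdims=True)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode requires a random generator")
    keep = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * keep


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, key_mask: np.ndarray | None):
    """Fused softmax(q k^T / sqrt(d_k)) v with an analytic backward pass.

    Shapes: q (..., L_q, d_k), k/v (..., L_k, d_k), broadcasting over
    leading (batch/head) axes.  ``key_mask`` broadcasts against the
    score shape; masked keys get exactly zero weight.  Fusing the whole
    attention into one graph node avoids materialising the score tensor
    several times per sublayer, which dominates runtime otherwise.

    Returns (output Tensor, weights Tensor); gradients flow through the
    output only — the weights are an inspection artefact.
    """
    from ._autodiff import _unbroadcast

    d_k = q.shape[-1]
    scale = 1.0 / np.sqrt(d_k)
    if (
        q.ndim == 4
        and k.ndim == 4
        and k.shape[0] == 1
        and q.shape[0] > 1
        and (key_mask is None or np.asarray(key_mask).size == np.asarray(key_mask).shape[-1])
    ):
        # keys shared across the batch and mask constant over queries:
        # merge batch and query rows into one GEMM per head
        return _shared_key_attention(q, k, v, key_mask, scale)
    s = np.matmul(q.data, np.swapaxes(k.data, -1, -2))
    s *= scale
    if key_mask is not None:
        key_mask = np.asarray(key_mask, dtype=s.dtype)
        s = s - (1.0 - key_mask) * _NEG_BIG
    s -= s.max(axis=-1, keepdims=True)
    np.exp(s, out=s)
    if key_mask is not None:
        s *= key_mask  # exactly zero on masked keys
    s /= s.sum(axis=-1, keepdims=True)
    weights = s  # (..., L_q, L_k), rows sum to 1 over unmasked keys
    out_data = np.matmul(weights, v.data)

    def bw(g, q=q, k=k, v=v, w=weights, scale=scale):
        gv = np.matmul(np.swapaxes(w, -1, -2), g)
        gw = np.matmul(g, np.swapaxes(v.data, -1, -2))
        gs = w * (gw - (gw * w).sum(axis=-1, keepdims=True))
        gs *= scale
        gq = np.matmul(gs, k.data)
        gk = np.matmul(np.swapaxes(gs, -1, -2), q.data)
        q._accumulate(_unbroadcast(gq, q.shape))
        k._accumulate(_unbroadcast(gk, k.shape))
        v._accumulate(_unbroadcast(gv, v.shape))

    out = Tensor._make(out_data, (q, k, v), bw)
    return out, Tensor(weights)


def _shared_key_attention(q: Tensor, k: Tensor, v: Tensor, key_mask, scale: float):
    """Fast path of :func:`scaled_dot_attention` for (B,h,L_q,d_k) queries
    against (1,h,L_k,d_k) keys: one GEMM per head over B*L_q rows."""
    B, h, Lq, dk = q.shape
    Lk = k.shape[-2]
    qd = np.ascontiguousarray(q.data.transpose(1, 0, 2, 3)).reshape(h, B * Lq, dk)
    kd, vd = k.data[0], v.data[0]
    s = np.matmul(qd, np.swapaxes(kd, -1, -2))  # (h, B*Lq, Lk)
    s *= scale
    mask_row = None
    if key_mask is not None:
        mask_row = np.asarray(key_mask, dtype=s.dtype).reshape(1, 1, Lk)
        s = s - (1.0 - mask_row) * _NEG_BIG
    s -= s.max(axis=-1, keepdims=True)
    np.exp(s, out=s)
    if mask_row is not None:
        s *= mask_row
    s /= s.sum(axis=-1, keepdims=True)
    out_data = np.matmul(s, vd).reshape(h, B, Lq, dk).transpose(1, 0, 2, 3)

    def bw(g, q=q, k=k, v=v, w=s, qd=qd, kd=kd, vd=vd):
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(h, B * Lq, dk)
        gv = np.matmul(np.swapaxes(w, -1, -2), gm)  # (h, Lk, dk)
        gw = np.matmul(gm, np.swapaxes(vd, -1, -2))  # (h, B*Lq, Lk)
        gs = w * (gw - (gw * w).sum(axis=-1, keepdims=True))
        gs *= scale
        gq = np.matmul(gs, kd).reshape(h, B, Lq, dk).transpose(1, 0, 2, 3)
        gk = np.matmul(np.swapaxes(gs, -1, -2), qd)  # (h, Lk, dk)
        q._accumulate(gq)
        k._accumulate(gk[None])
        v._accumulate(gv[None])

    out = Tensor._make(out_data, (q, k, v), bw)
    weights = s.reshape(h, B, Lq, Lk).transpose(1, 0, 2, 3)
    return out, Tensor(weights)


class Linear:
    """Affine map on the trailing axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class LayerNorm:
    """Per-position normalisation over the feature axis."""

    def __init__(self, d: int, eps: float = 1e-8):
        self.gain = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        normed = centred / (var + self.eps).sqrt()
        return normed * self.gain + self.bias

    def parameters(self):
        return [self.gain, self.bias]


class Conv1d:
    """Same-length 1-D convolution over axis 1 of a (B, L, C_in) tensor.

    Realised as an im2col gather followed by a single matmul; the kernel
    width must be odd so that zero padding of (k-1)/2 preserves length.
    """

    def __init__(self, d_in: int, d_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd to preserve sequence length")
        self.k = kernel_size
        self.d_in = d_in
        self.d_out = d_out
        scale = np.sqrt(2.0 / (kernel_size * d_in + d_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(kernel_size * d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.d_in:
            raise ValueError(f"expected {self.d_in} input channels, got {x.shape[-1]}")
        B, L = x.shape[0], x.shape[1]
        half = (self.k - 1) // 2
        xp = pad_axis(x, axis=1, before=half, after=half)
        idx = np.arange(L)[:, None] + np.arange(self.k)[None, :]  # (L, k)
        windows = xp[(slice(None), idx)]  # (B, L, k, d_in)
        flat = windows.reshape(B, L, self.k * self.d_in)
        return flat @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class MultiHeadAttention:
    """Scaled dot-product attention with head splitting and key masking."""

    def __init__(self, d_hid: int, n_heads: int, rng: np.random.Generator):
        if d_hid % n_heads != 0:
            raise ValueError("d_hid must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = d_hid // n_heads
        self.wq = Linear(d_hid, d_hid, rng)
        self.wk = Linear(d_hid, d_hid, rng)
        self.wv = Linear(d_hid, d_hid, rng)
        self.wo = Linear(d_hid, d_hid, rng)

    def _split(self, x: Tensor) -> Tensor:
        # (..., L, d_hid) -> (..., heads, L, d_k)
        *lead, L, _ = x.shape
        return x.reshape(*lead, L, self.n_heads, self.d_k).swapaxes(-2, -3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor, key_mask: np.ndarray):
        """Return (output, attention_weights).

        ``key_mask`` broadcasts against the score shape
        (..., heads, L_q, L_k); masked keys get exactly zero weight.
        """
        q = self._split(self.wq(query))
        k = self._split(self.wk(key))
        v = self._split(self.wv(value))
        mask = np.asarray(key_mask, dtype=key.data.dtype)
        if mask.ndim == key.ndim - 1:  # (..., L_k) -> broadcastable over heads/queries
            mask = mask[..., None, None, :]
        out, weights = scaled_dot_attention(q, k, v, mask)
        *lead, h, L, dk = out.shape
        merged = out.swapaxes(-2, -3).reshape(*lead, L, h * dk)
        return self.wo(merged), weights

    def parameters(self):
        return self.wq.parameters() + self.wk.parameters() + self.wv.parameters() + self.wo.parameters()


class FeedForward:
    """Position-wise feed-forward net: two width-1 convolutions with ReLU."""

    def __init__(self, d_hid: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d_hid, d_ff, rng)
        self.fc2 = Linear(d_ff, d_hid, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()
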