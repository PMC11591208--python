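"""Multi-head self-attention and the pre-norm Transformer block."""

from __future__ import annotations

import numpy as np

from .layers import GELU, LayerNorm, Linear, Module


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (N, T, D) tokens."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator | None = None) -> None:
        if dim % heads:
            raise ValueError("embedding dim must be divisible by the head count")
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        return x.reshape(n, t, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, t, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * d)

    def forward(self, x: np.ndarray) -> np.ndarray:
        qkv = self.qkv.forward(x)  # (N, T, 3D)
        q, k, v = np.split(qkv, 3, axis=-1)
        q, k, v = self._split(q), self._split(k), self._split(v)  # (N, H, T, dh)
        scale = 1.0 / np.sqrt(self.head_dim)
        scores = np.einsum("nhtd,nhsd->nhts", q, k) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        ctx = np.einsum("nhts,nhsd->nhtd", attn, v)
        self._cache = (q, k, v, attn.astype(np.float32))
        return self.proj.forward(self._merge(ctx).astype(np.float32))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        dctx = self._split(self.proj.backward(dy))
        dattn = np.einsum("nhtd,nhsd->nhts", dctx, v)
        dv = np.einsum("nhts,nhtd->nhsd", attn, dctx)
        # softmax backward
        dscores = (dattn - (dattn * attn).sum(axis=-1, keepdims=True)) * attn
        dscores *= 1.0 / np.sqrt(self.head_dim)
        dq = np.einsum("nhts,nhsd->nhtd", dscores, k)
        dk = np.einsum("nhts,nhtd->nhsd", dscores, q)
        dqkv = np.concatenate(
            [self._merge(dq), self._merge(dk), self._merge(dv)], axis=-1
        ).astype(np.float32)
        return self.qkv.backward(dqkv)


class TransformerBlock(Module):
    """Pre-norm block: x + MHSA(LN(x)); x + MLP(LN(x)) with GELU."""

    def __init__(
        self,
        dim: int,
        heads: int,
        mlp_ratio: float = 2.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.act = GELU()
        self.fc2 = Linear(hidden, dim, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x + self.attn.forward(self.norm1.forward(x))
        x = x + self.fc2.forward(self.act.forward(self.fc1.forward(self.norm2.forward(x))))
        return x.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d_mlp = self.norm2.backward(
            self.fc1.backward(self.act.backward(self.fc2.backward(dy)))
        )
        dy = dy + d_mlp
        d_attn = self.norm1.backward(self.attn.backward(dy))
        return (dy + d_attn).astype(np.float32)
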