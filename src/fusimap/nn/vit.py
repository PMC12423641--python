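"""Vision transformer classifier with attention capture for rollout.

Reference formulation: non-overlapping patch embedding, a learnable class
token and positional embedding, pre-norm transformer blocks with GELU
MLPs, and a linear head on the class token.  The default configuration for
91 x 128 frames uses patch size (7, 8) — a 13 x 16 grid of 208 patch
tokens plus the class token — 16 layers, 4 heads, embedding dimension 256.
Attention probabilities of every layer can be recorded during the forward
pass; attention rollout consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .ops import F32, GELU, Layer, LayerNorm, Linear, softmax, softmax_backward

__all__ = ["ViTSpec", "VisionTransformer", "build_vit"]


@dataclass
class ViTSpec:
    depth: int = 16
    heads: int = 4
    embed_dim: int = 256
    patch_size: Tuple[int, int] = (7, 8)
    mlp_ratio: float = 4.0
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 30

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must divide evenly across heads")


class _ParamBag(Layer):
    """Holds free parameters (class token, positional embedding)."""

    def __init__(self, **arrays: np.ndarray) -> None:
        super().__init__()
        for k, v in arrays.items():
            self.P[k] = v.astype(F32)
        self.zero_grad()


class _Attention(Layer):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.heads = heads
        self.dh = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.attn: Optional[np.ndarray] = None  # (B, heads, N, N) softmax probs

    def sublayers(self) -> List[Layer]:
        return [self.qkv, self.proj]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, N, D = x.shape
        qkv = self.qkv.forward(x).reshape(B, N, 3, self.heads, self.dh)
        q, k, v = (qkv[:, :, i].transpose(0, 2, 1, 3) for i in range(3))  # (B,h,N,dh)
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        p = softmax(scores, axis=-1)
        self.attn = p
        self._q, self._k, self._v = q, k, v
        ctx = p @ v  # (B,h,N,dh)
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj.forward(merged.astype(F32))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, N, D = dout.shape
        dmerged = self.proj.backward(dout)
        dctx = dmerged.reshape(B, N, self.heads, self.dh).transpose(0, 2, 1, 3)
        p, q, k, v = self.attn, self._q, self._k, self._v
        dp = dctx @ v.transpose(0, 1, 3, 2)
        dv = p.transpose(0, 1, 3, 2) @ dctx
        dscores = softmax_backward(p, dp, axis=-1) / np.sqrt(self.dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dqkv = np.stack([dq, dk, dv], axis=2)  # (B,h,3,N,dh)
        dqkv = dqkv.transpose(0, 3, 2, 1, 4).reshape(B, N, 3 * D)
        return self.qkv.backward(dqkv.astype(F32))


class _Block:
    """Pre-norm transformer block: x += attn(LN(x)); x += mlp(LN(x))."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator) -> None:
        hidden = int(dim * mlp_ratio)
        self.ln1 = LayerNorm(dim)
        self.attn = _Attention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.act = GELU()
        self.fc2 = Linear(hidden, dim, rng=rng)

    def sublayers(self) -> List[Layer]:
        return [self.ln1, *self.attn.sublayers(), self.ln2, self.fc1, self.act, self.fc2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x + self.attn.forward(self.ln1.forward(x))
        return x + self.fc2.forward(self.act.forward(self.fc1.forward(self.ln2.forward(x))))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.ln2.backward(
            self.fc1.backward(self.act.backward(self.fc2.backward(dout)))
        )
        dout = dout + d
        d = self.ln1.backward(self.attn.backward(dout))
        return dout + d


class VisionTransformer:
    def __init__(self, spec: ViTSpec, input_shape: Tuple[int, int], seed: int = 0) -> None:
        rows, cols = input_shape
        ph, pw = spec.patch_size
        if rows % ph or cols % pw:
            raise ValueError(
                f"image dims {input_shape} must be divisible by patch size {spec.patch_size}"
            )
        self.spec = spec
        self.input_shape = (rows, cols)
        self.grid = (rows // ph, cols // pw)
        self.n_patches = self.grid[0] * self.grid[1]
        rng = np.random.default_rng(seed)
        D = spec.embed_dim
        self.embed = Linear(ph * pw, D, rng=rng)
        self.tokens = _ParamBag(
            cls=rng.normal(0, 0.02, (1, 1, D)),
            pos=rng.normal(0, 0.02, (1, self.n_patches + 1, D)),
        )
        self.blocks = [_Block(D, spec.heads, spec.mlp_ratio, rng) for _ in range(spec.depth)]
        self.norm = LayerNorm(D)
        self.head = Linear(D, 2, rng=rng)

    # ------------------------------------------------------------------ core
    def _patchify(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 4:  # (B, 1, H, W)
            x = x[:, 0]
        B = x.shape[0]
        gh, gw = self.grid
        ph, pw = self.spec.patch_size
        patches = x.reshape(B, gh, ph, gw, pw).transpose(0, 1, 3, 2, 4)
        return patches.reshape(B, self.n_patches, ph * pw)

    def forward(self, x: np.ndarray, record_attn: bool = False) -> np.ndarray:
        tok = self.embed.forward(self._patchify(x))
        B = tok.shape[0]
        cls = np.broadcast_to(self.tokens.P["cls"], (B, 1, tok.shape[2]))
        seq = np.concatenate([cls, tok], axis=1) + self.tokens.P["pos"]
        seq = seq.astype(F32)
        self._attn_record: List[np.ndarray] = []
        for blk in self.blocks:
            seq = blk.forward(seq)
            if record_attn:
                self._attn_record.append(blk.attn.attn)
        self._cls_out = self.norm.forward(seq[:, 0])
        return self.head.forward(self._cls_out)

    def attention_stack(self) -> List[np.ndarray]:
        """Per-layer attention probabilities from the last recorded forward."""
        if not self._attn_record:
            raise RuntimeError("run forward(..., record_attn=True) first")
        return list(self._attn_record)

    def backward(self, dlogits: np.ndarray) -> None:
        d_cls = self.norm.backward(self.head.backward(dlogits))
        B = d_cls.shape[0]
        dseq = np.zeros((B, self.n_patches + 1, self.spec.embed_dim), dtype=F32)
        dseq[:, 0] = d_cls
        for blk in reversed(self.blocks):
            dseq = blk.backward(dseq)
        self.tokens.G["pos"] += dseq.sum(axis=0, keepdims=True)
        self.tokens.G["cls"] += dseq[:, :1].sum(axis=0, keepdims=True)
        self.embed.backward(dseq[:, 1:])

    def all_layers(self) -> List[Layer]:
        layers: List[Layer] = [self.embed, self.tokens]
        for blk in self.blocks:
            layers.extend(blk.sublayers())
        layers.extend([self.norm, self.head])
        return layers


def build_vit(
    spec: ViTSpec | None = None, input_shape: Tuple[int, int] = (91, 128), seed: int = 0
) -> VisionTransformer:
    return VisionTransformer(spec or ViTSpec(), input_shape, seed=seed)
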