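"""Genotype classifier head: patch tokens, transformer block, MLP, softmax.

The deepest encoder map (side ``input_size/16``, e.g. 24 for 384-pixel
inputs) is split into ``patch_grid**2`` non-overlapping square patches
(16 patches of side 6 at the default).  Each patch is flattened to a
token sequence — one token per pixel, embedding dimension = channel
count — and passed through a shared-weight transformer block (pre-norm
multi-head self-attention and feed-forward MLP with residuals).  Patches
are processed independently: attention is local to a patch and no
positional encoding is added.  The transformed tokens are reassembled
into a spatial map, average-pooled (kernel 4 at the default), flattened,
and reduced by a two-layer MLP to two logits whose softmax gives
(p_wild, p_mutant).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import NetworkConfig
from .nn import Tensor, avg_pool2d, log_softmax, relu, softmax

__all__ = [
    "self_attention",
    "multi_head_attention",
    "tokenize_patches",
    "untokenize_patches",
    "TransformerBlock",
    "ClassifierHead",
]


def self_attention(x: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor) -> Tensor:
    """Scaled dot-product attention over a (..., n_tokens, dim) sequence.

    Q = X W_q, K = X W_k, V = X W_v; output = softmax(Q K^T / sqrt(d)) V,
    where d is the key dimension.  Each softmax row sums to 1.
    """
    x, w_q, w_k, w_v = (Tensor._coerce(t) for t in (x, w_q, w_k, w_v))
    q, k, v = x @ w_q, x @ w_k, x @ w_v
    d = k.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (d ** -0.5)
    return softmax(scores, axis=-1) @ v


def multi_head_attention(x: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor,
                         w_o: Tensor, h: int) -> Tensor:
    """``h``-head attention: per-head projections, concat, output projection.

    ``w_q``/``w_k``/``w_v`` are (dim, dim) with the h head projections laid
    out in contiguous (dim/h)-column slabs; ``w_o`` maps the concatenated
    heads back to dim.
    """
    x = Tensor._coerce(x)
    dim = x.shape[-1]
    if dim % h:
        raise ValueError(f"embedding dim {dim} not divisible by {h} heads")
    dh = dim // h
    n = x.shape[-2]
    lead = x.shape[:-2]

    def split_heads(t: Tensor) -> Tensor:
        # (..., n, dim) -> (..., h, n, dh)
        t = t.reshape(*lead, n, h, dh)
        axes = tuple(range(len(lead))) + (t.ndim - 2, t.ndim - 3, t.ndim - 1)
        return t.transpose(*axes)

    q = split_heads(x @ w_q)
    k = split_heads(x @ w_k)
    v = split_heads(x @ w_v)
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (dh ** -0.5)
    heads = softmax(scores, axis=-1) @ v  # (..., h, n, dh)
    axes = tuple(range(len(lead))) + (heads.ndim - 2, heads.ndim - 3, heads.ndim - 1)
    merged = heads.transpose(*axes).reshape(*lead, n, dim)
    return merged @ w_o


def tokenize_patches(f: Tensor, patch_grid: int) -> Tensor:
    """Split an (N, C, H, W) map into per-patch token sequences.

    Returns (N, patch_grid**2, s**2, C) with s = H / patch_grid: patch
    p = gi * patch_grid + gj holds the tokens of the (gi, gj) tile in
    row-major pixel order.  Exactly inverted by :func:`untokenize_patches`.
    """
    n, c, hgt, wid = f.shape
    if hgt != wid:
        raise ValueError(f"feature map must be square, got {hgt}x{wid}")
    if hgt % patch_grid:
        raise ValueError(f"side {hgt} not divisible by patch_grid {patch_grid}")
    s = hgt // patch_grid
    t = f.reshape(n, c, patch_grid, s, patch_grid, s)
    t = t.transpose(0, 2, 4, 3, 5, 1)  # n, gi, gj, si, sj, c
    return t.reshape(n, patch_grid * patch_grid, s * s, c)


def untokenize_patches(tokens: Tensor, patch_grid: int) -> Tensor:
    """Inverse of :func:`tokenize_patches`: tokens back to (N, C, H, W)."""
    n, n_patches, n_tokens, c = tokens.shape
    s = int(round(np.sqrt(n_tokens)))
    t = tokens.reshape(n, patch_grid, patch_grid, s, s, c)
    t = t.transpose(0, 5, 1, 3, 2, 4)  # n, c, gi, si, gj, sj
    return t.reshape(n, c, patch_grid * s, patch_grid * s)


class TransformerBlock(nn.Module):
    """Pre-norm transformer: x + MHA(LN(x)); x + FF(LN(x))."""

    def __init__(self, rng, dim: int, num_heads: int, ff_mult: int = 4):
        super().__init__()
        self.num_heads = num_heads
        self.norm1 = nn.LayerNorm(dim)
        self.norm2 = nn.LayerNorm(dim)
        self.wq = nn.Linear(rng, dim, dim, bias=False)
        self.wk = nn.Linear(rng, dim, dim, bias=False)
        self.wv = nn.Linear(rng, dim, dim, bias=False)
        self.wo = nn.Linear(rng, dim, dim, bias=False)
        self.ff1 = nn.Linear(rng, dim, dim * ff_mult)
        self.ff2 = nn.Linear(rng, dim * ff_mult, dim)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(x)
        x = x + multi_head_attention(h, self.wq.weight, self.wk.weight,
                                     self.wv.weight, self.wo.weight, self.num_heads)
        h = self.norm2(x)
        return x + self.ff2(relu(self.ff1(h)))


class ClassifierHead(nn.Module):
    """Deepest feature map -> (p_wild, p_mutant)."""

    def __init__(self, rng, cfg: NetworkConfig):
        super().__init__()
        dim = cfg.stage_channels[-1]
        self.patch_grid = cfg.patch_grid
        self.pool_kernel = cfg.pool_kernel
        self.block = TransformerBlock(rng, dim, cfg.num_heads, cfg.ff_mult)
        side = cfg.input_size // 16 // cfg.pool_kernel
        self.flat_dim = dim * side * side
        self.mlp1 = nn.Linear(rng, self.flat_dim, cfg.mlp_hidden)
        self.mlp2 = nn.Linear(rng, cfg.mlp_hidden, 2)

    def logits(self, f: Tensor) -> Tensor:
        tokens = tokenize_patches(f, self.patch_grid)
        n, n_patches, n_tokens, c = tokens.shape
        # shared weights across patches; fold patches into the batch axis
        flat = tokens.reshape(n * n_patches, n_tokens, c)
        out = self.block(flat).reshape(n, n_patches, n_tokens, c)
        spatial = untokenize_patches(out, self.patch_grid)
        pooled = avg_pool2d(spatial, self.pool_kernel)
        return self.mlp2(relu(self.mlp1(pooled.reshape(n, self.flat_dim))))

    def forward(self, f: Tensor) -> Tensor:
        """Class probabilities (N, 2) ordered (wild, mutant)."""
        return softmax(self.logits(f), axis=-1)

    def log_probs(self, f: Tensor) -> Tensor:
        return log_softmax(self.logits(f), axis=-1)
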