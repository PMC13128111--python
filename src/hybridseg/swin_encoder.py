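"""Global-context branch: windowed and shifted-window multi-head attention.

Three stages of convolutional patch embedding (stride 4, then 2, then 2)
interleaved with pairs of attention blocks.  Within a pair, the first block
restricts multi-head self-attention to non-overlapping MxM token windows
(W-MSA); the second cyclically shifts the token grid by floor(M/2) before
windowing (SW-MSA) so information crosses window borders, using an additive
mask so tokens that came from different pre-shift regions cannot attend to
each other.  Each block computes, in order,

    z_hat = attn(LN(z)) + z        (windowed attention, residual)
    z_out = MLP(LN(z_hat)) + z_hat (two-layer MLP, residual)

with a learned relative-position bias table of (2M-1)^2 entries, shared
across heads, added to the attention logits.  Sharing the table (rather
than keeping one per head) makes the branch's parameter count exactly
invariant to the head split — attention weights are dim x dim however the
heads divide them.  Stage channels are (C, 2C, 4C) at strides (4, 8, 16).
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .cnn_encoder import FeaturePyramid
from .config import ModelConfig, validate_config

MASK_NEG = -1e4  # additive logit for masked pairs; exp underflows to 0 in f32


# ---------------------------------------------------------------------------
# window bookkeeping (pure array ops, exact inverses)
# ---------------------------------------------------------------------------


def window_partition(grid: nn.Tensor, m: int) -> nn.Tensor:
    """(B, H, W, D) token grid -> (B * nH * nW, M*M, D) windows."""
    b, h, w, d = grid.shape
    if h % m or w % m:
        raise ValueError(f"grid {h}x{w} not divisible by window size {m}")
    x = nn.reshape(grid, (b, h // m, m, w // m, m, d))
    x = nn.transpose(x, (0, 1, 3, 2, 4, 5))
    return nn.reshape(x, (b * (h // m) * (w // m), m * m, d))


def window_reverse(windows: nn.Tensor, m: int, h: int, w: int) -> nn.Tensor:
    """Exact inverse of :func:`window_partition`."""
    nwin = (h // m) * (w // m)
    b = windows.shape[0] // nwin
    x = nn.reshape(windows, (b, h // m, w // m, m, m, windows.shape[-1]))
    x = nn.transpose(x, (0, 1, 3, 2, 4, 5))
    return nn.reshape(x, (b, h, w, windows.shape[-1]))


def shifted_window_mask(h: int, w: int, m: int, shift: int) -> np.ndarray:
    """Additive attention mask for SW-MSA, shape (num_windows, M^2, M^2).

    After a cyclic shift by (-shift, -shift), each window may contain tokens
    from up to four different pre-shift regions; pairs from different regions
    get ``MASK_NEG``, same-region pairs 0.
    """
    region = np.zeros((h, w), dtype=np.int64)
    cnt = 0
    for hs in (slice(0, h - m), slice(h - m, h - shift), slice(h - shift, h)):
        for ws in (slice(0, w - m), slice(w - m, w - shift), slice(w - shift, w)):
            region[hs, ws] = cnt
            cnt += 1
    region = region.reshape(h // m, m, w // m, m).transpose(0, 2, 1, 3)
    region = region.reshape(-1, m * m)
    diff = region[:, :, None] - region[:, None, :]
    return np.where(diff != 0, np.float32(MASK_NEG), np.float32(0.0))


def relative_position_index(m: int) -> np.ndarray:
    """(M^2, M^2) indices into the (2M-1)^2 relative-position bias table."""
    coords = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]          # (2, M^2, M^2)
    rel = rel + (m - 1)
    return rel[0] * (2 * m - 1) + rel[1]


# ---------------------------------------------------------------------------
# attention block
# ---------------------------------------------------------------------------


class WindowAttention(nn.Module):
    """Multi-head scaled dot-product attention within MxM windows."""

    def __init__(self, dim: int, heads: int, m: int):
        super().__init__()
        if dim % heads:
            raise ValueError(f"head count {heads} does not divide dim {dim}")
        self.dim, self.heads, self.m = dim, heads, m
        self.head_dim = dim // heads
        self.scale = 1.0 / math.sqrt(self.head_dim)
        self.qkv = nn.Linear(dim, 3 * dim)
        self.proj = nn.Linear(dim, dim)
        self.rel_bias = nn.Parameter(nn.trunc_normal_(((2 * m - 1) ** 2,)))
        self._rel_index = relative_position_index(m)

    def forward(self, windows: nn.Tensor, mask: np.ndarray | None = None) -> nn.Tensor:
        nw, n, d = windows.shape
        if n != self.m * self.m:
            raise ValueError(f"expected {self.m * self.m} tokens/window, got {n}")
        qkv = self.qkv(windows)                                  # (nw, N, 3D)
        qkv = nn.reshape(qkv, (nw, n, 3, self.heads, self.head_dim))
        qkv = nn.transpose(qkv, (2, 0, 3, 1, 4))                 # (3,nw,h,N,hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        logits = nn.matmul(nn.mul(q, self.scale),
                           nn.transpose(k, (0, 1, 3, 2)), count=True)
        bias = self.rel_bias[self._rel_index.reshape(-1)]    # (N*N,)
        logits = nn.add(logits, nn.reshape(bias, (1, n, n)))
        if mask is not None:
            if mask.shape[-1] != n:
                raise ValueError("attention mask shape mismatch")
            nmask = mask.shape[0]
            logits = nn.reshape(logits, (nw // nmask, nmask, self.heads, n, n))
            logits = nn.add(logits, nn.Tensor(mask[None, :, None]))
            logits = nn.reshape(logits, (nw, self.heads, n, n))
        attn = nn.softmax(logits, axis=-1)
        out = nn.matmul(attn, v, count=True)                     # (nw,h,N,hd)
        out = nn.transpose(out, (0, 2, 1, 3))
        out = nn.reshape(out, (nw, n, d))
        return self.proj(out)


class SwinBlock(nn.Module):
    """One attention block (plain or shifted window) plus its MLP."""

    def __init__(self, dim: int, heads: int, m: int, shift: int,
                 mlp_ratio: float = 4.0):
        super().__init__()
        if shift >= m:
            raise ValueError("shift must be < window size")
        self.m, self.shift = m, shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, m)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden)
        self.fc2 = nn.Linear(hidden, dim)
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def _mask(self, h: int, w: int) -> np.ndarray | None:
        if self.shift == 0:
            return None
        key = (h, w)
        if key not in self._mask_cache:
            self._mask_cache[key] = shifted_window_mask(h, w, self.m, self.shift)
        return self._mask_cache[key]

    def forward(self, grid: nn.Tensor) -> nn.Tensor:
        b, h, w, d = grid.shape
        y = self.norm1(grid)
        if self.shift:
            y = nn.roll2d(y, (-self.shift, -self.shift), axes=(1, 2))
        wins = window_partition(y, self.m)
        wins = self.attn(wins, self._mask(h, w))
        y = window_reverse(wins, self.m, h, w)
        if self.shift:
            y = nn.roll2d(y, (self.shift, self.shift), axes=(1, 2))
        grid = nn.add(grid, y)
        z = self.norm2(grid)
        z = self.fc2(nn.gelu(self.fc1(z)))
        return nn.add(grid, z)


class PatchEmbed(nn.Module):
    """Strided conv turning a feature map into a (B, H, W, D) token grid."""

    def __init__(self, c_in: int, dim: int, patch: int):
        super().__init__()
        self.patch = patch
        self.conv = nn.Conv2d(c_in, dim, patch, patch, 0)
        self.norm = nn.LayerNorm(dim)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.shape[2] % self.patch or x.shape[3] % self.patch:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by patch {self.patch}")
        y = self.conv(x)                         # (B, D, H', W')
        y = nn.transpose(y, (0, 2, 3, 1))        # (B, H', W', D)
        return self.norm(y)


class SwinEncoder(nn.Module):
    """Three-stage windowed-attention encoder emitting a (C, 2C, 4C) pyramid."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        violations = validate_config(cfg)
        if violations:
            raise ValueError("invalid model config: " + "; ".join(violations))
        c, m = cfg.token_dim, cfg.window_size
        self.cfg = cfg
        self.embed1 = PatchEmbed(3, c, 4)
        self.embed2 = PatchEmbed(c, 2 * c, 2)
        self.embed3 = PatchEmbed(2 * c, 4 * c, 2)
        self.drop = nn.Dropout(cfg.dropout_swin)
        for s in range(3):
            dim = c * 2 ** s
            blocks = [SwinBlock(dim, cfg.heads[s], m,
                                0 if i % 2 == 0 else m // 2, cfg.mlp_ratio)
                      for i in range(cfg.depths[s])]
            setattr(self, f"stage{s + 1}", nn.Sequential(*blocks))

    def _stage(self, idx: int, grid: nn.Tensor) -> nn.Tensor:
        grid = getattr(self, f"stage{idx}")(grid)
        return self.drop(grid)

    def forward(self, x: nn.Tensor) -> FeaturePyramid:
        if x.shape[1] != 3:
            raise ValueError(f"expected 3 input channels, got {x.shape[1]}")
        g1 = self._stage(1, self.embed1(x))
        f1 = nn.transpose(g1, (0, 3, 1, 2))
        g2 = self._stage(2, self.embed2(f1))
        f2 = nn.transpose(g2, (0, 3, 1, 2))
        g3 = self._stage(3, self.embed3(f2))
        f3 = nn.transpose(g3, (0, 3, 1, 2))
        return FeaturePyramid(levels=(f1, f2, f3), source="swin")


def swin_forward(encoder: SwinEncoder, batch) -> FeaturePyramid:
    return encoder(batch)
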