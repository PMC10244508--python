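"""Hybrid CNN-transformer encoder.

The image first runs through a residual convolutional stem that halves
resolution four times, keeping the 1/2, 1/4 and 1/8 maps as skip features
for the decoder. The 1/16 map (optionally enriched by ASPP) is cut into
P x P patches, each flattened and linearly projected to a D-dimensional
token; a learned position table is added:

    Z0 = [x_p^1 E; ...; x_p^N E] + E_pos,   N = H'W' / P^2

and a stack of pre-norm transformer layers follows:

    z'_n = MSA(LN(z_{n-1})) + z_{n-1}
    z_n  = MLP(LN(z'_n)) + z'_n

The residual wiring means a layer whose MSA and MLP output projections are
zero is exactly the identity — a structural fact the tests pin down.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import (Module, Sequential, Conv2d, Linear, LayerNorm, BatchNorm2d,
                 GroupNorm, ReLU, Dropout, Tensor)
from .aspp import ASPP

__all__ = ["EncoderConfig", "CNNStem", "sequentialize", "unflatten",
           "PatchEmbedding", "TransformerLayer", "HybridEncoder"]


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    """Architectural hyperparameters of the encoder.

    The default mirrors the R50+ViT-B/16 hybrid (12 layers, 12 heads,
    D=768, MLP 3072, patch size 1 on the 1/16 map); ``tiny()`` is a
    CPU-friendly configuration used throughout the tests.
    """

    stem_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    n_layers: int = 12
    hidden_dim: int = 768
    n_heads: int = 12
    mlp_dim: int = 3072
    patch_size: int = 1
    dropout: float = 0.1
    in_channels: int = 1
    norm: str = "batch"

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValueError(f"hidden_dim {self.hidden_dim} must be divisible "
                             f"by n_heads {self.n_heads}")
        if len(self.stem_widths) != 4:
            raise ValueError("stem_widths must list four stage widths")

    @staticmethod
    def tiny(**overrides) -> "EncoderConfig":
        base = dict(stem_widths=(8, 16, 32, 64), n_layers=2, hidden_dim=64,
                    n_heads=4, mlp_dim=128, patch_size=1, dropout=0.0)
        base.update(overrides)
        return EncoderConfig(**base)


def _norm(channels: int, kind: str) -> Module:
    if kind == "batch":
        return BatchNorm2d(channels)
    if kind == "group":
        return GroupNorm(min(8, channels), channels)
    raise ValueError(f"unknown norm kind {kind!r}")


class _ResBlock(Module):
    """Basic residual block: two 3x3 convs with an identity shortcut."""

    def __init__(self, channels: int, norm: str):
        super().__init__()
        self.body = Sequential(
            Conv2d(channels, channels, 3, padding=1), _norm(channels, norm), ReLU(),
            Conv2d(channels, channels, 3, padding=1), _norm(channels, norm))

    def forward(self, x: Tensor) -> Tensor:
        return (self.body(x) + x).relu()


class _DownStage(Module):
    """Stride-2 3x3 conv + norm + ReLU followed by one residual block."""

    def __init__(self, cin: int, cout: int, norm: str):
        super().__init__()
        self.down = Sequential(Conv2d(cin, cout, 3, stride=2, padding=1),
                               _norm(cout, norm), ReLU())
        self.res = _ResBlock(cout, norm)

    def forward(self, x: Tensor) -> Tensor:
        return self.res(self.down(x))


class CNNStem(Module):
    """Residual stem: four stride-2 stages; skips at 1/2, 1/4, 1/8 scale."""

    def __init__(self, cfg: EncoderConfig):
        super().__init__()
        w = cfg.stem_widths
        self.stage1 = _DownStage(cfg.in_channels, w[0], cfg.norm)
        self.stage2 = _DownStage(w[0], w[1], cfg.norm)
        self.stage3 = _DownStage(w[1], w[2], cfg.norm)
        self.stage4 = _DownStage(w[2], w[3], cfg.norm)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        B, C, H, W = x.shape
        if H % 16 or W % 16:
            raise ValueError(f"input size {H}x{W} must be divisible by 16; "
                             f"pad the image first")
        s1 = self.stage1(x)      # 1/2
        s2 = self.stage2(s1)     # 1/4
        s3 = self.stage3(s2)     # 1/8
        deep = self.stage4(s3)   # 1/16
        return deep, [s1, s2, s3]


def sequentialize(f: Tensor, patch_size: int) -> tuple[Tensor, tuple[int, int]]:
    """Cut a B x C x H' x W' map into N = H'W'/P^2 flattened P x P patches.

    Patches are ordered row-major; each row of the result is one patch's
    P^2*C values. Lossless: :func:`unflatten` inverts it.
    """
    B, C, H, W = f.shape
    P = patch_size
    if H % P or W % P:
        raise ValueError(f"patch size {P} must divide feature size {H}x{W}")
    gh, gw = H // P, W // P
    x = f.reshape(B, C, gh, P, gw, P)
    x = x.transpose(0, 2, 4, 3, 5, 1)          # B, gh, gw, P, P, C
    return x.reshape(B, gh * gw, P * P * C), (gh, gw)


def unflatten(patches: Tensor, grid_shape: tuple[int, int], patch_size: int,
              channels: int) -> Tensor:
    """Inverse of :func:`sequentialize`."""
    B, N, L = patches.shape
    gh, gw = grid_shape
    P = patch_size
    if N != gh * gw or L != P * P * channels:
        raise ValueError(f"token block {patches.shape} inconsistent with "
                         f"grid {grid_shape}, P={P}, C={channels}")
    x = patches.reshape(B, gh, gw, P, P, channels)
    x = x.transpose(0, 5, 1, 3, 2, 4)
    return x.reshape(B, channels, gh * P, gw * P)


class PatchEmbedding(Module):
    """Linear patch projection E plus learned position table E_pos."""

    def __init__(self, patch_dim: int, n_tokens: int, hidden_dim: int):
        super().__init__()
        self.n_tokens = n_tokens
        self.proj = Linear(patch_dim, hidden_dim)
        self.pos = Tensor(np.zeros((n_tokens, hidden_dim)), requires_grad=True)

    def reset_parameters(self, rng):
        self.pos.data[...] = rng.normal(0.0, 0.02, self.pos.shape)

    def forward(self, patches: Tensor) -> Tensor:
        if patches.shape[1] != self.n_tokens:
            raise ValueError(f"expected {self.n_tokens} tokens, "
                             f"got {patches.shape[1]}")
        return self.proj(patches) + self.pos


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int):
        super().__init__()
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = Linear(dim, dim)
        self.k = Linear(dim, dim)
        self.v = Linear(dim, dim)
        self.out = Linear(dim, dim)

    def _split(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        return x.reshape(B, N, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, z: Tensor) -> Tensor:
        B, N, D = z.shape
        q, k, v = self._split(self.q(z)), self._split(self.k(z)), self._split(self.v(z))
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        att = att.softmax(axis=-1)
        y = (att @ v).transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.out(y)


class TransformerLayer(Module):
    """Pre-norm residual transformer block (MSA then MLP)."""

    def __init__(self, dim: int, n_heads: int, mlp_dim: int, dropout: float = 0.0,
                 ln_eps: float = 1e-6):
        super().__init__()
        self.ln1 = LayerNorm(dim, eps=ln_eps)
        self.msa = MultiHeadSelfAttention(dim, n_heads)
        self.ln2 = LayerNorm(dim, eps=ln_eps)
        self.fc1 = Linear(dim, mlp_dim)
        self.fc2 = Linear(mlp_dim, dim)
        self.drop = Dropout(dropout)

    def forward(self, z: Tensor) -> Tensor:
        if not np.all(np.isfinite(z.data)):
            raise FloatingPointError("non-finite values entering transformer layer")
        z = self.drop(self.msa(self.ln1(z))) + z
        z = self.drop(self.fc2(self.drop(self.fc1(self.ln2(z)).gelu()))) + z
        return z


class HybridEncoder(Module):
    """CNN stem -> (optional ASPP) -> patch tokens -> transformer stack."""

    def __init__(self, cfg: EncoderConfig, input_size: tuple[int, int],
                 use_aspp: bool = True):
        super().__init__()
        self.cfg = cfg
        self.use_aspp = use_aspp
        H, W = input_size
        if H % 16 or W % 16:
            raise ValueError("input size must be divisible by 16")
        deep_c = cfg.stem_widths[-1]
        hp, wp = H // 16, W // 16
        P = cfg.patch_size
        if hp % P or wp % P:
            raise ValueError(f"patch size {P} must divide the 1/16 "
                             f"feature size {hp}x{wp}")
        self.n_tokens = (hp // P) * (wp // P)
        assert self.n_tokens == hp * wp // (P * P)
        self.grid_shape = (hp // P, wp // P)
        self.stem = CNNStem(cfg)
        if use_aspp:
            self.aspp = ASPP(deep_c, deep_c, norm=cfg.norm)
        self.embed = PatchEmbedding(P * P * deep_c, self.n_tokens, cfg.hidden_dim)
        layers = [TransformerLayer(cfg.hidden_dim, cfg.n_heads, cfg.mlp_dim,
                                   cfg.dropout) for _ in range(cfg.n_layers)]
        for i, lyr in enumerate(layers):
            setattr(self, f"layer{i}", lyr)
        self.layers = layers
        self.ln_final = LayerNorm(cfg.hidden_dim)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        deep, skips = self.stem(x)
        if self.use_aspp:
            deep = self.aspp(deep)
        patches, grid = sequentialize(deep, self.cfg.patch_size)
        z = self.embed(patches)
        for lyr in self.layers:
            z = lyr(z)
        return self.ln_final(z), skips
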