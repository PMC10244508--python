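"""Channel attention, pixel attention, and their sequential composition.

Channel attention (CBAM-style) squeezes each feature map to two global
descriptors — average-pooled and max-pooled — pushes both through one
shared bottleneck MLP, sums, and gates every channel with a sigmoid:

    M_c(F) = sigma(W1(relu(W0(avgpool(F)))) + W1(relu(W0(maxpool(F)))))

giving a C x 1 x 1 map. Pixel attention is a single 1x1 convolution plus
sigmoid, giving a full C x H x W map:

    M_p(F) = sigma(f_1x1(F))

The CPAT block applies them sequentially, each multiplied into the
features it gates:

    F'  = M_c(F) * F          (per-channel scaling)
    F'' = M_p(F') * F'        (elementwise)

Because every gate lies strictly in (0, 1), CPAT can only attenuate:
|F''| <= |F'| <= |F| elementwise.
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Linear, Conv2d, Tensor

__all__ = ["ChannelAttention", "PixelAttention", "CPAT"]


class ChannelAttention(Module):
    """Per-channel sigmoid gates from pooled descriptors and a shared MLP.

    Parameters
    ----------
    channels : feature channels C.
    reduction : bottleneck ratio r; the hidden width is max(C // r, 1).
    bias : whether the MLP layers carry bias terms.
    strict_literal : if True, the max-pool branch skips the bottleneck layer
        W0 and goes through W1 alone — a non-standard variant kept for
        comparison; the default shares the full two-layer MLP across both
        branches (the CBAM design).
    """

    def __init__(self, channels: int, reduction: int = 16, bias: bool = True,
                 strict_literal: bool = False):
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction ratio must be >= 1")
        self.channels = channels
        hidden = max(channels // reduction, 1)
        self.w0 = Linear(channels, hidden, bias=bias)
        self.w1 = Linear(hidden, channels, bias=bias)
        self.strict_literal = strict_literal
        if strict_literal:
            self.w1_direct = Linear(channels, channels, bias=bias)

    def forward(self, f: Tensor) -> Tensor:
        """Return the C x 1 x 1 attention map for a B x C x H x W input."""
        if f.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {f.shape[1]}")
        avg = f.mean(axis=(2, 3))          # (B, C)
        mx = f.reshape(f.shape[0], f.shape[1], -1).max(axis=2)
        a = self.w1(self.w0(avg).relu())
        if self.strict_literal:
            m = self.w1_direct(mx)
        else:
            m = self.w1(self.w0(mx).relu())
        gate = (a + m).sigmoid()
        return gate.reshape(f.shape[0], self.channels, 1, 1)


class PixelAttention(Module):
    """Per-pixel, per-channel sigmoid gates from a 1x1 convolution."""

    def __init__(self, channels: int, bias: bool = True):
        super().__init__()
        self.channels = channels
        self.conv = Conv2d(channels, channels, kernel_size=1, bias=bias)

    def forward(self, f: Tensor) -> Tensor:
        """Return the C x H x W attention map, same shape as the input."""
        if f.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {f.shape[1]}")
        return self.conv(f).sigmoid()


class CPAT(Module):
    """Sequential channel-then-pixel attention, each gate multiplied in."""

    def __init__(self, channels: int, reduction: int = 16, bias: bool = True):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction=reduction, bias=bias)
        self.pixel = PixelAttention(channels, bias=bias)

    def forward(self, f: Tensor) -> Tensor:
        f1 = self.channel(f) * f       # broadcast C x 1 x 1 over H x W
        f2 = self.pixel(f1) * f1
        return f2


def cpat_param_count(channels: int, reduction: int = 16, bias: bool = True) -> int:
    """Closed-form trainable-parameter total of one CPAT block."""
    hidden = max(channels // reduction, 1)
    mlp = channels * hidden + hidden * channels
    pix = channels * channels
    if bias:
        mlp += hidden + channels
        pix += channels
    return mlp + pix
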