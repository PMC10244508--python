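"""Atrous Spatial Pyramid Pooling (ASPP).

Parallel 3x3 convolutions at dilation rates 2, 4 and 8 (plus an optional
1x1 branch), concatenated and fused by a 1x1 convolution. Dilation inserts
``rate - 1`` zeros between kernel taps, so a k x k kernel covers an
effective window of ``k + (k-1)(rate-1)`` pixels — rates 2/4/8 turn a 3x3
kernel into 5/9/17-pixel receptive fields at unchanged cost and, because
"same" padding is used throughout and no pooling is involved, at unchanged
spatial resolution. This suits lesions whose extent varies and which grow
thin extensions (into the internal auditory canal) that a single receptive
field misses.
"""

from __future__ import annotations

from .nn import Module, Conv2d, BatchNorm2d, GroupNorm, ReLU, Sequential, Tensor, concat

__all__ = ["effective_kernel_size", "ASPP"]


def effective_kernel_size(k: int, rate: int) -> int:
    """Effective window of a k x k convolution dilated by `rate`.

    k + (k - 1)(rate - 1); ordinary convolution is rate 1.
    """
    if k < 1 or rate < 1:
        raise ValueError(f"kernel size and rate must be >= 1, got k={k}, rate={rate}")
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    return k + (k - 1) * (rate - 1)


def _norm(channels: int, kind: str) -> Module:
    if kind == "batch":
        return BatchNorm2d(channels)
    if kind == "group":
        return GroupNorm(min(8, channels), channels)
    raise ValueError(f"unknown norm kind {kind!r}")


class ASPP(Module):
    """Parallel dilated branches fused by a 1x1 convolution.

    Branch width is ``out_channels // n_branches`` and the fuse restores
    ``out_channels``; each branch carries norm + ReLU. There is deliberately
    no pooling branch: the point of the module is multi-scale context
    without resolution loss.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rates: tuple[int, ...] = (2, 4, 8),
                 include_1x1_branch: bool = True, norm: str = "batch"):
        super().__init__()
        if list(rates) != sorted(set(rates)) or any(r < 1 for r in rates):
            raise ValueError("rates must be strictly increasing and >= 1")
        self.rates = tuple(rates)
        self.include_1x1_branch = include_1x1_branch
        n_branches = len(rates) + (1 if include_1x1_branch else 0)
        width = max(out_channels // n_branches, 1)
        branches = []
        if include_1x1_branch:
            branches.append(Sequential(
                Conv2d(in_channels, width, 1), _norm(width, norm), ReLU()))
        for r in rates:
            branches.append(Sequential(
                Conv2d(in_channels, width, 3, padding=r, dilation=r),
                _norm(width, norm), ReLU()))
        for i, br in enumerate(branches):
            setattr(self, f"branch{i}", br)
        self.branches = branches
        self.fuse = Sequential(Conv2d(n_branches * width, out_channels, 1),
                               _norm(out_channels, norm), ReLU())

    def forward(self, f: Tensor) -> Tensor:
        outs = [br(f) for br in self.branches]
        return self.fuse(concat(outs, axis=1))
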