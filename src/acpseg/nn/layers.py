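"""Neural-network modules on top of the autodiff tensor.

Mirrors the familiar Module/parameter idiom: submodules and parameters
register themselves through ``__setattr__``, ``state_dict`` flattens the
tree into name -> ndarray, and every layer knows how to (re)initialise
itself from an explicit ``numpy.random.Generator`` so that weight init is
a pure function of the seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Identity", "Linear", "Conv2d", "LayerNorm",
    "BatchNorm2d", "GroupNorm", "ReLU", "GELU", "Dropout",
]


class Module:
    """Base class: parameter/submodule registry plus train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- persistence ----------------------------------------------------------

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats); override."""
        return {}

    def named_buffers(self, prefix: str = ""):
        for name, b in self.buffers().items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        out.update({k: b.copy() for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(params) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"state_dict missing keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data[...] = state[k]
        for k, b in bufs.items():
            b[...] = state[k]

    # -- init -----------------------------------------------------------------

    def reset_parameters(self, rng: np.random.Generator) -> None:
        """Per-layer init; default no-op, containers recurse via initialize."""

    def initialize(self, rng: np.random.Generator) -> "Module":
        """Deterministically initialise the whole tree in registration order."""
        for m in self.modules():
            m.reset_parameters(rng)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Dropout(Module):
    """Inverted dropout; draws from the generator installed by the trainer.

    With no generator installed (or rate 0) it is the identity, so inference
    and unit tests are deterministic by default.
    """

    def __init__(self, rate: float = 0.0):
        super().__init__()
        self.rate = float(rate)
        self.rng: np.random.Generator | None = None

    def forward(self, x):
        if not self.training or self.rate <= 0.0 or self.rng is None:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(np.zeros((in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def reset_parameters(self, rng):
        bound = np.sqrt(6.0 / (self.in_features + self.out_features))
        self.weight.data[...] = rng.uniform(-bound, bound, self.weight.shape)
        if self.bias is not None:
            self.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.weight = Tensor(
            np.zeros((out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def reset_parameters(self, rng):
        fan_in = self.in_channels * self.kernel_size ** 2
        std = np.sqrt(2.0 / fan_in)  # He init, ReLU networks
        self.weight.data[...] = rng.normal(0.0, std, self.weight.shape)
        if self.bias is not None:
            self.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class LayerNorm(Module):
    """Normalise over the trailing feature axis (token sequences)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def reset_parameters(self, rng):
        self.gamma.data[...] = 1.0
        self.beta.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def reset_parameters(self, rng):
        self.gamma.data[...] = 1.0
        self.beta.data[...] = 0.0
        self.running_mean[...] = 0.0
        self.running_var[...] = 1.0

    def forward(self, x: Tensor) -> Tensor:
        g = self.gamma.reshape(1, self.channels, 1, 1)
        b = self.beta.reshape(1, self.channels, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mu.data.ravel())
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var.data.ravel())
            return xc * (var + self.eps) ** -0.5 * g + b
        mu = Tensor(self.running_mean.reshape(1, self.channels, 1, 1))
        var = Tensor(self.running_var.reshape(1, self.channels, 1, 1))
        return (x - mu) * (var + self.eps) ** -0.5 * g + b


class GroupNorm(Module):
    """Batch-independent alternative to BatchNorm2d (batch size 1 training)."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"groups={groups} must divide channels={channels}")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def reset_parameters(self, rng):
        self.gamma.data[...] = 1.0
        self.beta.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        xg = x.reshape(B, self.groups, C // self.groups * H * W)
        mu = xg.mean(axis=-1, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = (xc * (var + self.eps) ** -0.5).reshape(B, C, H, W)
        return y * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)
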