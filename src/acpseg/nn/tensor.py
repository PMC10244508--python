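"""Array-valued reverse-mode automatic differentiation.

A deliberately small tape-based engine in the micrograd style, but over
numpy arrays: every :class:`Tensor` wraps an ``ndarray`` and records the
closure needed to push gradients back to its parents.  The operation set
is exactly what an encoder-decoder segmentation network needs — broadcast
arithmetic, (batched) matmul, axis reductions, dilated 2-D convolution via
im2col, bilinear up-sampling as a pair of interpolation matrices, softmax
and log-softmax — nothing more.

Gradient conventions follow the usual deep-learning ones: broadcasting in
the forward pass becomes summation in the backward pass; ties in ``max``
split the gradient evenly among the maximisers.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concat"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # collapse broadcast (size-1) axes
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the bookkeeping for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}{tag})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(out):
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            self._accum(-out.grad)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(out):
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, n: float):
        if isinstance(n, Tensor):
            raise TypeError("only scalar exponents are supported")

        def backward(out):
            self._accum(out.grad * n * self.data ** (n - 1.0))

        return Tensor._make(self.data ** n, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(out):
            g = out.grad
            a, b = self.data, other.data
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul backward needs >=2-D operands")
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(out):
            self._accum(out.grad.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(out):
            self._accum(out.grad.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)

        def backward(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == m).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)
            self._accum(mask * g)

        data = m if keepdims or axis is None else np.squeeze(m, axis=axis)
        if axis is None and not keepdims:
            data = np.squeeze(m)
        return Tensor._make(data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(out):
            self._accum(out.grad * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out):
            self._accum(out.grad * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(out):
            self._accum(out.grad * (1.0 - t * t))

        return Tensor._make(t, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        phi = 0.5 * (1.0 + _erf(x / _SQRT2))

        def backward(out):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            self._accum(out.grad * (phi + x * pdf))

        return Tensor._make(x * phi, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(out):
            self._accum(out.grad * e)

        return Tensor._make(e, (self,), backward)

    def log(self):
        def backward(out):
            self._accum(out.grad / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(out):
            g = out.grad
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return Tensor._make(s, (self,), backward)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        sm = np.exp(ls)

        def backward(out):
            g = out.grad
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(ls, (self,), backward)

    # -- structured ops -------------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, dilation: int = 1) -> "Tensor":
        """2-D cross-correlation, NCHW layout, square stride/pad/dilation.

        Implemented by an as_strided im2col view; the backward pass scatters
        per-tap contributions with strided slice additions, which is safe
        (no overlapping writes within one tap).
        """
        x = self.data
        w = weight.data
        if x.ndim != 4 or w.ndim != 4:
            raise ValueError("conv2d expects 4-D input and weight (NCHW, OIKK)")
        B, C, H, W = x.shape
        O, Cw, kh, kw = w.shape
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kh}x{kw}")
        if Cw != C:
            raise ValueError(f"channel mismatch: input has {C}, weight expects {Cw}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Hp, Wp = xp.shape[2], xp.shape[3]
        eh, ew = dilation * (kh - 1) + 1, dilation * (kw - 1) + 1
        OH = (Hp - eh) // stride + 1
        OW = (Wp - ew) // stride + 1
        if OH < 1 or OW < 1:
            raise ValueError("kernel larger than padded input")
        s = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp,
            shape=(B, C, kh, kw, OH, OW),
            strides=(s[0], s[1], s[2] * dilation, s[3] * dilation,
                     s[2] * stride, s[3] * stride),
        )
        cols2 = cols.reshape(B, C * kh * kw, OH * OW)  # copies
        w2 = w.reshape(O, C * kh * kw)
        out = (w2 @ cols2).reshape(B, O, OH, OW)
        if bias is not None:
            out = out + bias.data.reshape(1, O, 1, 1)

        def backward(outt):
            g = outt.grad  # (B, O, OH, OW)
            g2 = g.reshape(B, O, OH * OW)
            if weight.requires_grad:
                gw = np.einsum("bon,bkn->ok", g2, cols2).reshape(O, C, kh, kw)
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gxp = np.zeros((B, C, Hp, Wp))
                for i in range(kh):
                    ii = i * dilation
                    for j in range(kw):
                        jj = j * dilation
                        # (B,C,OH,OW) contribution of tap (i, j)
                        t = np.einsum("oc,bohw->bchw", w[:, :, i, j], g)
                        gxp[:, :, ii:ii + OH * stride:stride,
                            jj:jj + OW * stride:stride] += t
                if padding:
                    gxp = gxp[:, :, padding:Hp - padding, padding:Wp - padding]
                self._accum(gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, backward)

    def upsample_bilinear(self, scale: int = 2) -> "Tensor":
        """Bilinear up-sampling (align_corners=False) of an NCHW tensor."""
        B, C, H, W = self.shape
        My = _interp_matrix(H, H * scale)
        Mx = _interp_matrix(W, W * scale)
        out = np.einsum("ih,bchw->bciw", My, self.data)
        out = np.einsum("jw,bciw->bcij", Mx, out)

        def backward(outt):
            g = np.einsum("jw,bcij->bciw", Mx, outt.grad)
            g = np.einsum("ih,bciw->bchw", My, g)
            self._accum(g)

        return Tensor._make(out, (self,), backward)

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D linear-interpolation matrix, align_corners=False, edge-clamped."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = src - i0
    M = np.zeros((n_out, n_in))
    M[np.arange(n_out), i0] += 1.0 - w
    M[np.arange(n_out), i1] += w
    return M


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, differentiable."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.grad.ndim
            idx[axis] = slice(a, b)
            t._accum(out.grad[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)
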