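"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the ConvMixer-ECA forward pass and its
attention variants need: broadcasting arithmetic, (grouped, strided) 1-D
convolution, circular padding along an axis, GELU / sigmoid / ReLU /
softmax, reductions, batched matmul, and numerically stable classification
losses.  Gradients are accumulated by topological traversal of the tape.

All tensors are float64.  The engine is deliberately small; every op's
backward pass is validated against central-difference gradients in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.special import erf

__all__ = ["Tensor", "cat"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def pad_circular(self, pad: int, axis: int = -1):
        """Wrap-pad `pad` entries on each side of `axis`."""
        if pad == 0:
            return self
        n = self.data.shape[axis]
        if pad > n:
            raise ValueError(f"circular pad {pad} exceeds axis length {n}")
        idx = np.mod(np.arange(-pad, n + pad), n)
        out_data = np.take(self.data, idx, axis=axis)

        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(
                    acc,
                    tuple(
                        idx if ax == (axis % self.data.ndim) else slice(None)
                        for ax in range(self.data.ndim)
                    ),
                    g,
                )
                self._accum(acc)

        return self._make(out_data, (self,), backward)

    def pad_zero(self, pad: int, axis: int = -1):
        if pad == 0:
            return self
        width = [(0, 0)] * self.data.ndim
        width[axis] = (pad, pad)
        out_data = np.pad(self.data, width)
        sl = tuple(
            slice(pad, -pad) if ax == (axis % self.data.ndim) else slice(None)
            for ax in range(self.data.ndim)
        )

        def backward(g):
            if self.requires_grad:
                self._accum(g[sl])

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if self.requires_grad:
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy())
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        argmax = np.expand_dims(self.data.argmax(axis=axis), axis)

        def backward(g):
            if self.requires_grad:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                acc = np.zeros_like(self.data)
                np.put_along_axis(acc, argmax, np.take_along_axis(acc, argmax, axis) + g, axis)
                self._accum(acc)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ activations
    def gelu(self):
        """Exact Gaussian-error linear unit: x * Phi(x)."""
        phi = 0.5 * (1.0 + erf(self.data * _INV_SQRT2))
        out_data = self.data * phi
        pdf = _INV_SQRT2PI * np.exp(-0.5 * self.data**2)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (phi + self.data * pdf))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ convolution
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0, groups: int = 1):
        """Grouped 1-D cross-correlation.

        self: [B, C_in, L]; weight: [C_out, C_in // groups, K];
        output: [B, C_out, (L + 2*padding - K)//stride + 1].
        """
        weight = self._lift(weight)
        x = self.pad_zero(padding, axis=-1) if padding else self
        B, C_in, L = x.data.shape
        C_out, C_in_g, K = weight.data.shape
        if C_in % groups or C_out % groups or C_in // groups != C_in_g:
            raise ValueError(
                f"incompatible conv shapes: x has {C_in} channels, weight "
                f"{weight.data.shape}, groups={groups}"
            )
        L_out = (L - K) // stride + 1
        if L_out < 1:
            raise ValueError(f"input length {L} shorter than kernel {K}")
        parents = (x, weight) if bias is None else (x, weight, bias)

        if groups == 1 and K == 1 and stride == 1:
            # pointwise: a position-shared linear map over channels
            w2 = weight.data[:, :, 0]                       # [C_out x C_in]
            out_data = np.tensordot(w2, x.data, axes=([1], [1])).transpose(1, 0, 2)
            if bias is not None:
                out_data = out_data + bias.data.reshape(1, C_out, 1)

            def backward(g):
                if weight.requires_grad:
                    dw = np.tensordot(g, x.data, axes=([0, 2], [0, 2]))
                    weight._accum(dw[:, :, None])
                if bias is not None and bias.requires_grad:
                    bias._accum(g.sum(axis=(0, 2)).reshape(bias.data.shape))
                if x.requires_grad:
                    x._accum(np.tensordot(w2.T, g, axes=([1], [1])).transpose(1, 0, 2))

            return self._make(out_data, parents, backward)

        if groups == C_in == C_out:
            # depthwise: each channel convolved with its own kernel
            s0, s1, s2 = x.data.strides
            cols = as_strided(x.data, (B, C_in, L_out, K), (s0, s1, s2 * stride, s2))
            wk = weight.data[:, 0, :]                       # [C x K]
            out_data = np.einsum("bclk,ck->bcl", cols, wk, optimize=True)
            if bias is not None:
                out_data = out_data + bias.data.reshape(1, C_out, 1)

            def backward(g):
                if weight.requires_grad:
                    dw = np.einsum("bcl,bclk->ck", g, cols, optimize=True)
                    weight._accum(dw[:, None, :])
                if bias is not None and bias.requires_grad:
                    bias._accum(g.sum(axis=(0, 2)).reshape(bias.data.shape))
                if x.requires_grad:
                    dx = np.zeros_like(x.data)
                    for i in range(K):
                        dx[:, :, i : i + stride * L_out : stride] += g * wk[None, :, i, None]
                    x._accum(dx)

            return self._make(out_data, parents, backward)

        G = groups
        xg = x.data.reshape(B, G, C_in_g, L)
        s0, s1, s2, s3 = xg.strides
        cols = as_strided(xg, (B, G, C_in_g, L_out, K), (s0, s1, s2, s3 * stride, s3))
        wg = weight.data.reshape(G, C_out // G, C_in_g, K)
        out_data = np.einsum("bgclk,gock->bgol", cols, wg, optimize=True)
        out_data = np.ascontiguousarray(out_data).reshape(B, C_out, L_out)
        if bias is not None:
            out_data = out_data + bias.data.reshape(1, C_out, 1)

        def backward(g):
            gg = g.reshape(B, G, C_out // G, L_out)
            if weight.requires_grad:
                dw = np.einsum("bgol,bgclk->gock", gg, cols, optimize=True)
                weight._accum(np.ascontiguousarray(dw).reshape(C_out, C_in_g, K))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)).reshape(bias.data.shape))
            if x.requires_grad:
                dx = np.zeros_like(xg)
                for i in range(K):
                    # positions i, i+stride, ... receive kernel tap i
                    contrib = np.einsum("bgol,goc->bgcl", gg, wg[:, :, :, i], optimize=True)
                    dx[:, :, :, i : i + stride * L_out : stride] += contrib
                x._accum(dx.reshape(B, C_in, L))

        return self._make(out_data, parents, backward)

    # ----------------------------------------------------------------- losses
    def bce_with_logits(self, targets: np.ndarray):
        """Mean binary cross-entropy over all elements; numerically stable."""
        t = np.asarray(targets, dtype=np.float64)
        x = self.data
        loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
        out_data = loss.mean()
        n = x.size

        def backward(g):
            if self.requires_grad:
                sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
                self._accum(g * (sig - t) / n)

        return self._make(out_data, (self,), backward)

    def softmax_cross_entropy(self, labels: np.ndarray):
        """Mean cross-entropy of softmax(self) against integer labels.

        self: [B, N] logits; labels: [B] ints.
        """
        y = np.asarray(labels, dtype=np.int64)
        x = self.data
        shifted = x - x.max(axis=1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        logp = shifted - logz
        B = x.shape[0]
        out_data = -logp[np.arange(B), y].mean()

        def backward(g):
            if self.requires_grad:
                p = np.exp(logp)
                p[np.arange(B), y] -= 1.0
                self._accum(g * p / B)

        return self._make(out_data, (self,), backward)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = tuple(
                        slice(lo, hi) if ax == (axis % g.ndim) else slice(None)
                        for ax in range(g.ndim)
                    )
                    t._accum(g[sl])

        out._backward = backward
    return out
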