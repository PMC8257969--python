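"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the convolutional-recurrent
mixture-density model needs: broadcast-aware elementwise arithmetic,
matrix products, the usual nonlinearities, reductions, reshaping,
gather/scatter (for frame deduplication) and an im2col unfold (for
convolution).  Gradients are accumulated on a dynamically built tape and
released after ``backward``.

Every operation is checked against central finite differences in the
test-suite; the contract is float32 forward values and float32
gradients correct to ~1e-3 relative.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32, copy=False)
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32)  # own a copy
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def softplus(self):
        # numerically stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        out_data = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * sig)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def square(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * 2.0 * self.data)

        return Tensor._make(self.data**2, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def logsumexp(self, axis=-1, keepdims=False):
        """Stable log-sum-exp; the max shift is treated as a constant."""
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(np.squeeze(out.data, axis=axis).shape)
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def take(self, indices: np.ndarray):
        """Gather rows along axis 0; backward scatter-adds (handles repeats)."""
        indices = np.asarray(indices)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, indices, g)
                self._accum(full)

        return Tensor._make(self.data[indices], (self,), backward)

    @staticmethod
    def concat(tensors, axis=0):
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
        )

    def unfold2d(self, kernel: int, stride: int, pad: int):
        """im2col: (B, C, H, W) -> (B, out_h*out_w, C*kernel*kernel)."""
        B, C, H, W = self.data.shape
        x = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        out_h = (H + 2 * pad - kernel) // stride + 1
        out_w = (W + 2 * pad - kernel) // stride + 1
        s = x.strides
        windows = np.lib.stride_tricks.as_strided(
            x,
            shape=(B, C, out_h, out_w, kernel, kernel),
            strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        )
        cols = (
            windows.transpose(0, 2, 3, 1, 4, 5)
            .reshape(B, out_h * out_w, C * kernel * kernel)
            .copy()
        )

        def backward(g):
            if not self.requires_grad:
                return
            gcols = g.reshape(B, out_h, out_w, C, kernel, kernel).transpose(
                0, 3, 1, 2, 4, 5
            )
            gx = np.zeros_like(x)
            for ki in range(kernel):
                for kj in range(kernel):
                    gx[
                        :,
                        :,
                        ki : ki + out_h * stride : stride,
                        kj : kj + out_w * stride : stride,
                    ] += gcols[:, :, :, :, ki, kj]
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            self._accum(gx)

        return Tensor._make(cols, (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release the tape
        for node in topo:
            node._parents = ()
            node._backward = None
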