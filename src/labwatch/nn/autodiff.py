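"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` on a scalar loss propagates gradients through the recorded
graph in reverse topological order.  The operation set is exactly what the
sequence architectures in this package need: broadcast-aware arithmetic,
(batched) matmul, the usual nonlinearities, reductions, slicing/concat/
reshape/transpose, a dilated causal 1-D convolution, and a numerically
stable binary-cross-entropy-with-logits loss.

Everything runs single-threaded on the CPU and is bitwise deterministic for
a fixed operation order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "bce_with_logits", "conv1d_causal"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS (graphs from the LSTM loop exceed recursion limits)
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_graph(self) -> None:
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out_data = self.data ** p
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))
        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))
        return Tensor._from_op(np.matmul(self.data, other.data),
                               (self, other), backward)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)
        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))
        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = np.where(self.data >= 0,
                            1.0 / (1.0 + np.exp(-np.abs(self.data))),
                            np.exp(-np.abs(self.data))
                            / (1.0 + np.exp(-np.abs(self.data))))
        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))
        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        pos = self.data > 0
        def backward(g):
            if self.requires_grad:
                self._accum(g * pos)
        return Tensor._from_op(self.data * pos, (self,), backward)

    def leaky_relu(self, alpha: float = 0.2):
        slope = np.where(self.data > 0, 1.0, alpha)
        def backward(g):
            if self.requires_grad:
                self._accum(g * slope)
        return Tensor._from_op(self.data * slope, (self,), backward)

    def sin(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * np.cos(self.data))
        return Tensor._from_op(np.sin(self.data), (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims),
                               (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))
        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)
        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        return Tensor._from_op(self.data[idx], (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        # max-shift is a constant w.r.t. the gradient
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)
    return Tensor._from_op(np.concatenate(datas, axis=axis), tuple(tensors),
                           backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        pieces = np.moveaxis(g, axis, 0)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)
    return Tensor._from_op(np.stack([t.data for t in tensors], axis=axis),
                           tuple(tensors), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits, stable for large |z|.

    loss = mean( max(z,0) - z*y + log(1 + exp(-|z|)) );
    d loss / d z = (sigmoid(z) - y) / n.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = per.size
    def backward(g):
        if logits.requires_grad:
            s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                         np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
            logits._accum(g * (s - y) / n)
    return Tensor._from_op(np.array(per.mean()), (logits,), backward)


def conv1d_causal(x: Tensor, weight: Tensor, bias: Tensor,
                  dilation: int = 1) -> Tensor:
    """Dilated causal 1-D convolution preserving sequence length.

    ``x`` is (N, T, Cin), ``weight`` is (K, Cin, Cout), ``bias`` (Cout,).
    The input is left-padded with (K-1)*dilation zero steps so output step t
    depends only on inputs at steps <= t.
    """
    K = weight.data.shape[0]
    pad = (K - 1) * dilation
    N, T, Cin = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, 0), (0, 0)))
    # cols[n, t, k, c] = xp[n, t + k*dilation, c]
    cols = np.stack([xp[:, k * dilation: k * dilation + T, :]
                     for k in range(K)], axis=2)
    out_data = np.einsum("ntkc,kco->nto", cols, weight.data) + bias.data

    def backward(g):
        if weight.requires_grad:
            weight._accum(np.einsum("ntkc,nto->kco", cols, g))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = np.einsum("nto,kco->ntkc", g, weight.data)
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, k * dilation: k * dilation + T, :] += dcols[:, :, k, :]
            x._accum(dxp[:, pad:, :])
    return Tensor._from_op(out_data, (x, weight, bias), backward)
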