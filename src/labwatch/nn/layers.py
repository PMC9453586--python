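"""Neural-network layers on top of the autodiff engine.

Provides the building blocks the forecasting architectures use: dense
layers, an LSTM, causal/dilated 1-D convolutions with residual TCN blocks,
batch and layer normalization, multi-head self-attention and a learned
linear-plus-periodic time embedding.  Weight initialization is Glorot
uniform drawn from an explicit numpy Generator, so identical seeds build
identical networks.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv1d_causal

__all__ = [
    "Module", "Dense", "LSTM", "Conv1D", "BatchNorm", "LayerNorm",
    "MultiHeadSelfAttention", "TimeEncoding", "TCNBlock",
]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def set_training(self, training: bool) -> None:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(training)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(training)
        if hasattr(self, "training"):
            self.training = training

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) == 3:  # conv kernels (K, Cin, Cout)
        fan_in = shape[0] * shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.W = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W + self.b
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "leaky_relu":
            out = out.leaky_relu()
        elif self.activation == "tanh":
            out = out.tanh()
        elif self.activation == "sigmoid":
            out = out.sigmoid()
        return out


class LSTM(Module):
    """Single-layer LSTM; returns the final hidden state (N, units).

    Gate order in the stacked weight matrices is (input, forget, cell,
    output); the forget-gate bias starts at 1 to ease gradient flow early
    in training.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx = Tensor(_glorot(rng, n_in, 4 * units), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, units, 4 * units), requires_grad=True)
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        N, T, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((N, u)))
        c = Tensor(np.zeros((N, u)))
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = z[:, :u].sigmoid()
            f = z[:, u:2 * u].sigmoid()
            g = z[:, 2 * u:3 * u].tanh()
            o = z[:, 3 * u:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class Conv1D(Module):
    """1-D convolution along time; causal (left) zero padding keeps length."""

    def __init__(self, n_in: int, n_filters: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1,
                 activation: str | None = None):
        self.W = Tensor(_glorot(rng, kernel_size, n_in, n_filters),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_filters), requires_grad=True)
        self.dilation = dilation
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = conv1d_causal(x, self.W, self.b, dilation=self.dilation)
        if self.activation == "relu":
            out = out.relu()
        elif self.activation == "leaky_relu":
            out = out.leaky_relu()
        return out


class BatchNorm(Module):
    """Feature-wise batch normalization on (N, F) activations.

    Batch statistics in training; exponential running averages (momentum
    0.9) at inference.
    """

    def __init__(self, n_features: int, eps: float = 1e-5,
                 momentum: float = 0.9):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        else:
            xhat = ((x - Tensor(self.running_mean))
                    * Tensor(1.0 / np.sqrt(self.running_var + self.eps)))
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    """Normalization over the last axis (per token), as used in attention."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) * (x - mu)).mean(axis=-1, keepdims=True)
        return (x - mu) * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``n_heads`` heads."""

    def __init__(self, n_in: int, d_model: int, n_heads: int,
                 rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Dense(n_in, d_model, rng)
        self.k = Dense(n_in, d_model, rng)
        self.v = Dense(n_in, d_model, rng)
        self.out = Dense(d_model, d_model, rng)

    def _split(self, t: Tensor, N: int, T: int) -> Tensor:
        return t.reshape(N, T, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor) -> Tensor:
        N, T, _ = x.shape
        q = self._split(self.q(x), N, T)
        k = self._split(self.k(x), N, T)
        v = self._split(self.v(x), N, T)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(
            N, T, self.n_heads * self.d_head)
        return self.out(ctx)


class TimeEncoding(Module):
    """Learned time-to-vector embedding: one linear + (width-1) periodic
    components of the step index, concatenated feature-wise with the input.

    Component 0 is ``w0 * t + b0``; component i is ``sin(w_i * t + b_i)``.
    """

    def __init__(self, width: int, rng: np.random.Generator):
        if width < 2:
            raise ValueError("time-encoding width must be >= 2 "
                             "(one linear + at least one periodic component)")
        self.width = width
        self.w = Tensor(rng.uniform(-1, 1, size=width), requires_grad=True)
        self.b = Tensor(rng.uniform(-1, 1, size=width), requires_grad=True)

    def encode(self, step_indices: np.ndarray) -> Tensor:
        """Embedding matrix (T, width) for integer step indices."""
        t = Tensor(np.asarray(step_indices, dtype=np.float64)[:, None])  # (T,1)
        arg = t * self.w + self.b                                        # (T,W)
        lin = arg[:, :1]
        per = arg[:, 1:].sin()
        return concat([lin, per], axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        """Concatenate the embedding onto every sequence of a (N,T,F) batch."""
        N, T, _ = x.shape
        emb = self.encode(np.arange(T))                 # (T, width)
        tiled = emb.reshape(1, T, self.width) + Tensor(np.zeros((N, T, self.width)))
        return concat([x, tiled], axis=2)


class TCNBlock(Module):
    """Residual block of two dilated causal convolutions (LeakyReLU)."""

    def __init__(self, n_in: int, n_filters: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        self.conv1 = Conv1D(n_in, n_filters, kernel_size, rng,
                            dilation=dilation, activation="leaky_relu")
        self.conv2 = Conv1D(n_filters, n_filters, kernel_size, rng,
                            dilation=dilation, activation="leaky_relu")
        self.proj = (Dense(n_in, n_filters, rng) if n_in != n_filters else None)

    def __call__(self, x: Tensor) -> Tensor:
        out = self.conv2(self.conv1(x))
        res = self.proj(x) if self.proj is not None else x
        return (out + res).leaky_relu()
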