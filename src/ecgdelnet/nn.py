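"""Compact numpy engine for small 1D convolutional networks.

Implements the handful of layers a 1D U-Net needs — same-padded convolution,
depthwise (separable) convolution, batch normalization, ReLU/sigmoid, spatial
(channel) dropout, max pooling and nearest-neighbour upsampling — each with an
explicit reverse-mode ``backward`` so the whole network can be trained with
Adam on a CPU.  Tensors are ``(batch, channels, length)`` float64 arrays.

Every layer instance appears at one fixed position in a network; ``forward``
caches what ``backward`` needs, so a backward call must follow the matching
forward call of the same training step.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1d",
    "DepthwiseConv1d",
    "SeparableConv1d",
    "BatchNorm1d",
    "ReLU",
    "Sigmoid",
    "SpatialDropout",
    "MaxPool1d",
    "Upsample1d",
    "Adam",
    "he_init",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-normal initialization, suited to ReLU networks."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    """Base class: parameterless identity."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1D convolution (stride 1, odd kernel)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = Param(he_init(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        ps = [self.weight]
        if self.bias is not None:
            ps.append(self.bias)
        return ps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pad = self.kernel_size // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad))) if pad else x
        self._xp = xp
        T = x.shape[2]
        W = self.weight.value
        y = np.einsum("oc,bct->bot", W[:, :, 0], xp[:, :, 0:T], optimize=True)
        for k in range(1, self.kernel_size):
            y += np.einsum("oc,bct->bot", W[:, :, k], xp[:, :, k:k + T], optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        T = dy.shape[2]
        pad = self.kernel_size // 2
        W = self.weight.value
        dxp = np.zeros_like(xp)
        for k in range(self.kernel_size):
            self.weight.grad[:, :, k] += np.einsum(
                "bot,bct->oc", dy, xp[:, :, k:k + T], optimize=True)
            dxp[:, :, k:k + T] += np.einsum("oc,bot->bct", W[:, :, k], dy, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2))
        return dxp[:, :, pad:pad + T] if pad else dxp


class DepthwiseConv1d(Layer):
    """Per-channel same-padded convolution (the spatial half of a separable conv)."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.channels = channels
        self.kernel_size = kernel_size
        self.weight = Param(he_init(rng, (channels, kernel_size), kernel_size))
        self.bias = Param(np.zeros(channels))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pad = self.kernel_size // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        self._xp = xp
        T = x.shape[2]
        W = self.weight.value
        y = W[None, :, 0:1] * xp[:, :, 0:T]
        for k in range(1, self.kernel_size):
            y += W[None, :, k:k + 1] * xp[:, :, k:k + T]
        return y + self.bias.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        T = dy.shape[2]
        pad = self.kernel_size // 2
        W = self.weight.value
        dxp = np.zeros_like(xp)
        for k in range(self.kernel_size):
            self.weight.grad[:, k] += (dy * xp[:, :, k:k + T]).sum(axis=(0, 2))
            dxp[:, :, k:k + T] += W[None, :, k:k + 1] * dy
        self.bias.grad += dy.sum(axis=(0, 2))
        return dxp[:, :, pad:pad + T]


class SeparableConv1d(Layer):
    """Depthwise-separable convolution: depthwise spatial filter then 1x1 pointwise mix."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.depthwise = DepthwiseConv1d(in_channels, kernel_size, rng)
        self.pointwise = Conv1d(in_channels, out_channels, 1, rng)

    def params(self) -> list[Param]:
        return self.depthwise.params() + self.pointwise.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.pointwise.forward(self.depthwise.forward(x, training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.depthwise.backward(self.pointwise.backward(dy))


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, training, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, training, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.value[None, :, None] * inv_std[None, :, None]
        if not training:
            return dy * g
        dxhat = dy * self.gamma.value[None, :, None]
        term = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True))
        return term * inv_std[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # evaluate on the negative side only: numerically stable for large |x|
        pos = x >= 0
        z = np.exp(np.where(pos, -x, x))
        self._y = np.where(pos, 1.0 / (1.0 + z), z / (1.0 + z))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class SpatialDropout(Layer):
    """Channel dropout: whole feature channels are zeroed during training,
    survivors rescaled by 1/(1-p); identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = 1.0
            return x
        keep = self.rng.random((x.shape[0], x.shape[1], 1)) >= self.p
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel = stride = ``size``)."""

    def __init__(self, size: int = 2):
        self.size = size
        self._arg = None
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, T = x.shape
        if T % self.size != 0:
            raise ValueError(f"length {T} not divisible by pool size {self.size}")
        xr = x.reshape(B, C, T // self.size, self.size)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, T = self._shape
        dxr = np.zeros((B, C, T // self.size, self.size))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        return dxr.reshape(B, C, T)


class Upsample1d(Layer):
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.repeat(x, self.factor, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, T = dy.shape
        return dy.reshape(B, C, T // self.factor, self.factor).sum(axis=3)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
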