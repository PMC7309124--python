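"""Minimal CPU neural-network layers (numpy, float32).

Exactly the layer inventory the multi-resolution ASPP classifier needs:
stride-1 (optionally dilated) convolution, batch normalization, ReLU,
2x2 max pooling, global average pooling with broadcast upsampling,
inverted dropout and a fully connected head. Every layer implements an
explicit ``forward``/``backward`` pair.

All spatial tensors use the channels-last (N, H, W, C) layout so
convolutions read and write contiguous memory; convolutions run either as
one GEMM over an im2col matrix (few input channels) or as a loop of
per-tap GEMMs (many channels), whichever moves less memory.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Broadcast2d",
    "Dropout",
    "Flatten",
    "Linear",
    "glorot_uniform",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """One trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Stride-1 2-D convolution with symmetric zero padding and dilation.

    With ``padding = dilation * (kernel - 1) // 2`` (the default) the
    spatial size is preserved for odd kernels. Weights are stored as
    ``(out_channels, in_channels, k, k)`` with Glorot-uniform init.
    """

    _IM2COL_MAX_COLS = 256  # build the full im2col matrix below this c*k*k

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        dilation: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.k = kernel
        self.d = dilation
        self.p = dilation * (kernel - 1) // 2 if padding is None else padding
        fan_in = in_channels * kernel * kernel
        fan_out = out_channels * kernel * kernel
        self.weight = Param(
            glorot_uniform((out_channels, in_channels, kernel, kernel), fan_in, fan_out, rng),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), name=f"{name}.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _taps(self):
        return ((i, j) for i in range(self.k) for j in range(self.k))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        k, d, p = self.k, self.d, self.p
        ho = h + 2 * p - d * (k - 1)
        wo = w + 2 * p - d * (k - 1)
        if ho <= 0 or wo <= 0:
            raise ValueError("kernel reach exceeds the padded input")
        xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        xp[:, p : p + h, p : p + w, :] = x
        self._xp = xp

        wmat = self.weight.value
        co = wmat.shape[0]
        if c * k * k <= self._IM2COL_MAX_COLS:
            # (taps*c, rows) layout: row-contiguous writes per tap
            cols = np.empty((k * k * c, n * ho * wo), dtype=np.float32)
            for t, (i, j) in enumerate(self._taps()):
                cols[t * c : (t + 1) * c, :] = (
                    xp[:, i * d : i * d + ho, j * d : j * d + wo, :].reshape(-1, c).T
                )
            self._cols = cols
            wrows = wmat.transpose(0, 2, 3, 1).reshape(co, k * k * c)
            acc = np.ascontiguousarray((wrows @ cols).T)
        else:
            self._cols = None
            acc = np.zeros((n * ho * wo, co), dtype=np.float32)
            for i, j in self._taps():
                tap = xp[:, i * d : i * d + ho, j * d : j * d + wo, :].reshape(-1, c)
                acc += tap @ wmat[:, :, i, j].T
        acc += self.bias.value
        return acc.reshape(n, ho, wo, co)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, ho, wo, co = dy.shape
        k, d, p = self.k, self.d, self.p
        xp = self._xp
        c = xp.shape[-1]
        dy_flat = dy.reshape(-1, co)
        self.bias.grad += dy_flat.sum(axis=0)
        wmat = self.weight.value

        dxp = np.zeros_like(xp)
        if self._cols is not None:
            dw = self._cols @ dy_flat  # (k*k*c, co)
            self.weight.grad += dw.reshape(k, k, c, co).transpose(3, 2, 0, 1)
            wrows = wmat.transpose(0, 2, 3, 1).reshape(co, k * k * c)
            dcols = wrows.T @ dy_flat.T  # (k*k*c, rows)
            for t, (i, j) in enumerate(self._taps()):
                dxp[:, i * d : i * d + ho, j * d : j * d + wo, :] += (
                    dcols[t * c : (t + 1) * c, :].T.reshape(n, ho, wo, c)
                )
            self._cols = None
        else:
            for i, j in self._taps():
                tap = xp[:, i * d : i * d + ho, j * d : j * d + wo, :].reshape(-1, c)
                self.weight.grad[:, :, i, j] += dy_flat.T @ tap
                dtap = dy_flat @ wmat[:, :, i, j]
                dxp[:, i * d : i * d + ho, j * d : j * d + wo, :] += dtap.reshape(n, ho, wo, c)
        h = xp.shape[1] - 2 * p
        w = xp.shape[2] - 2 * p
        self._xp = None
        if p == 0:
            return dxp
        return np.ascontiguousarray(dxp[:, p : p + h, p : p + w, :])


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, name: str = "bn") -> None:
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=np.float32), name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2), dtype=np.float32)
            var = x.var(axis=(0, 1, 2), dtype=np.float32)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        if train:
            self._xhat = xhat
            self._inv = inv
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (dxhat - sum_dxhat / m - xhat * (sum_dxhat_xhat / m)) * inv
        self._xhat = None
        return dx.astype(np.float32, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = dy * self._mask
        self._mask = None
        return out


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2.

    On ties the gradient goes to the first cell in scan order (ties occur
    with quantized 8-bit inputs; the choice is deterministic).
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        cells = np.stack(
            [x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :], x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]],
            axis=-1,
        )  # (n, h/2, w/2, c, 4)
        self._argmax = cells.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(cells, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dcells = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dcells, self._argmax[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, 0::2, 0::2, :] = dcells[..., 0]
        dx[:, 0::2, 1::2, :] = dcells[..., 1]
        dx[:, 1::2, 0::2, :] = dcells[..., 2]
        dx[:, 1::2, 1::2, :] = dcells[..., 3]
        self._argmax = None
        return dx


class GlobalAvgPool(Layer):
    """Adaptive average pooling down to a single 1x1 cell per channel."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2), keepdims=True, dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return (np.broadcast_to(dy, (n, h, w, c)) / (h * w)).astype(np.float32)


class Broadcast2d(Layer):
    """Upsample a 1x1 map back to a target spatial size.

    Bilinear upsampling of a single cell is a constant fill, so this is the
    exact resize used after the pooled ASPP branch.
    """

    def __init__(self, target_hw: tuple[int, int]) -> None:
        self.target_hw = target_hw

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1:3] != (1, 1):
            raise ValueError("Broadcast2d expects a 1x1 spatial input")
        n, _, _, c = x.shape
        h, w = self.target_hw
        return np.broadcast_to(x, (n, h, w, c)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.sum(axis=(1, 2), keepdims=True).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None, name: str = "fc") -> None:
        rng = rng or np.random.default_rng(0)
        self.weight = Param(
            glorot_uniform((in_features, out_features), in_features, out_features, rng),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_features, dtype=np.float32), name=f"{name}.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dy
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value.T
        self._x = None
        return dx.astype(np.float32, copy=False)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)
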