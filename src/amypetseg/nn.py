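"""Minimal NumPy neural-network primitives with analytic backpropagation.

Implements exactly the building blocks the 2D U-Net needs — same-padded 3x3
convolution, ReLU, 2x2 max pooling, 2x2 stride-2 transposed convolution,
channel concatenation — plus the Adam optimizer.  Each layer caches what its
backward pass needs; gradients accumulate into per-parameter ``grad`` buffers.

Array convention: batches are ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "MaxPool2d",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)

    @property
    def size(self) -> int:
        return self.value.size


class Conv2d:
    """3x3 (or kxk) convolution with 'same' zero padding, stride 1.

    Same-padding keeps the output the same spatial size as the input so
    predictions can be overlaid directly on the original slices.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        # He initialization for ReLU networks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias")
        self.kernel_size = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}"
            )
        k, p = self.kernel_size, self.kernel_size // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xpad, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
        y = np.tensordot(win, self.weight.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        y += self.bias.value[None, :, None, None]
        self._cache = (xpad.shape, win)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xpad_shape, win = self._cache  # type: ignore[misc]
        k, p = self.kernel_size, self.kernel_size // 2
        n, _, h, w = dy.shape
        self.weight.grad += np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxpad = np.zeros(xpad_shape)
        for i in range(k):
            for j in range(k):
                contrib = np.tensordot(dy, self.weight.value[:, :, i, j], axes=([1], [0]))
                dxpad[:, :, i : i + h, j : j + w] += contrib.transpose(0, 3, 1, 2)
        return dxpad[:, :, p : p + h, p : p + w] if p else dxpad


class ConvTranspose2d:
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator | None = None,
        name: str = "upconv",
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_in = in_channels  # each output pixel sees one input pixel per tap
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_channels, out_channels, 2, 2))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}"
            )
        n, _, h, w = x.shape
        tmp = np.tensordot(x, self.weight.value, axes=([1], [0]))  # (N,H,W,Cout,2,2)
        y = tmp.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.out_channels, 2 * h, 2 * w)
        y = np.ascontiguousarray(y)
        y += self.bias.value[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache  # type: ignore[assignment]
        n, _, h, w = x.shape
        dyr = dy.reshape(n, self.out_channels, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        self.weight.grad += np.tensordot(x, dyr, axes=([0, 2, 3], [0, 1, 2]))
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dyr, self.weight.value, axes=([3, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU:
    """Element-wise rectified linear unit."""

    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2d:
    """2x2 max pooling, stride 2; gradient routed to the argmax position."""

    def __init__(self) -> None:
        self._cache: tuple | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, c, h, w), idx = self._cache  # type: ignore[misc]
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class Adam:
    """Adam optimizer with standard bias correction."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
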