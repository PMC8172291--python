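"""Minimal NumPy neural-network engine for the segmentation U-Net.

Layers store their learnable arrays as :class:`Param` objects and implement
``forward``/``backward`` explicitly; convolutions are expressed as im2col +
GEMM so the heavy lifting stays inside BLAS.  The engine covers exactly
what the U-Net needs: 3×3 and 1×1 convolutions with bias, batch
normalization, leaky ReLU, 2×2 max pooling, 2× bilinear upsampling,
channel concatenation, and a sigmoid output.

All activations are NCHW float arrays; the dtype is configurable
(float32 for speed, float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "MaxPool2d",
    "BilinearUp2d",
    "Sigmoid",
    "SGD",
]


class Param:
    """A learnable array with its gradient and momentum buffer."""

    __slots__ = ("data", "grad", "vel")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)
        self.vel = np.zeros_like(data)

    @property
    def size(self) -> int:
        return self.data.size


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) → (N·H·W, C·k·k) patch matrix with zero padding."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2d:
    """Same-size convolution (stride 1, zero padding (k−1)/2) with bias.

    Initialization is Kaiming-uniform on the weights (fan-in, leaky-ReLU
    gain) and uniform ±1/√fan_in on the bias.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32, negative_slope: float = 0.01):
        if k not in (1, 3):
            raise ValueError("engine supports 1x1 and 3x3 convolutions")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = (k - 1) // 2
        fan_in = c_in * k * k
        gain = np.sqrt(2.0 / (1.0 + negative_slope**2))
        bound = gain * np.sqrt(3.0 / fan_in)
        w = rng.uniform(-bound, bound, size=(c_out, c_in, k, k))
        b = rng.uniform(-1.0 / np.sqrt(fan_in), 1.0 / np.sqrt(fan_in), size=(c_out,))
        self.weight = Param(w.astype(dtype))
        self.bias = Param(b.astype(dtype))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        wmat = self.weight.data.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.bias.data
        if train:
            self._cols, self._shape = cols, x.shape
        else:
            self._cols = None
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c_out, h, w = grad.shape
        gmat = grad.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        self.weight.grad += (gmat.T @ self._cols).reshape(self.weight.data.shape)
        self.bias.grad += gmat.sum(axis=0)
        # grad wrt input = convolution of grad with spatially-flipped,
        # channel-transposed weights — reuse the same im2col + GEMM path
        wback = self.weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_in, C_out, k, k)
        gcols = _im2col(grad, self.k, self.pad)
        dx = gcols @ wback.reshape(self.c_in, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class BatchNorm2d:
    """Per-feature batch normalization with learnable scale and shift.

    Training mode normalizes with batch statistics and tracks running
    moments (not learnable); eval mode uses the running moments.
    """

    def __init__(self, c: int, dtype=np.float32, eps: float = 1e-5, momentum: float = 0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Param(np.ones(c, dtype=dtype))
        self.bias = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            unbiased = var * m / max(m - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.weight.data[None, :, None, None] * xhat + self.bias.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.weight.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.weight.data[None, :, None, None]
        gsum = gxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        gdot = (gxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return inv[None, :, None, None] * (gxhat - gsum / m - xhat * gdot / m)


class LeakyReLU:
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, grad, self.slope * grad)


class MaxPool2d:
    """2×2 max pooling (stride 2); ties route the gradient to the first max."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._idx, self._shape
        self._idx = None
        buf = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(buf, idx[..., None], grad[..., None], axis=-1)
        buf = buf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return buf.reshape(n, c, h, w)


def _bilinear_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """1-D linear-interpolation matrix (half-pixel centers, clamped edges)."""
    m = np.zeros((n_out, n_in), dtype=np.float64)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[i, lo] += 1.0 - t
        m[i, hi] += t
    return m.astype(dtype)


class BilinearUp2d:
    """2× bilinear upsampling, expressed as two 1-D interpolation matrices."""

    def __init__(self, dtype=np.float32):
        self.dtype = dtype
        self._mats: dict[int, np.ndarray] = {}

    def params(self) -> list[Param]:
        return []

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _bilinear_matrix(2 * n_in, n_in, self.dtype)
        return self._mats[n_in]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        mh, mw = self._mat(h), self._mat(w)
        out = x @ mw.T          # (N, C, H, 2W)
        out = np.matmul(mh, out)  # (N, C, 2H, 2W)
        if train:
            self._dims = (h, w)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h, w = self._dims
        mh, mw = self._mat(h), self._mat(w)
        dx = np.matmul(mh.T, grad)
        return dx @ mw

class Sigmoid:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out, self._out = self._out, None
        return grad * out * (1.0 - out)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            p.vel[...] = self.momentum * p.vel + g
            p.data[...] = p.data - self.lr * p.vel
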