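"""Feed-forward layers: convolution, pooling, batch norm, dense, dropout.

Convolutions are 3x3, stride 1, zero-padded to 'same' size, computed as
nine shifted GEMMs (one per kernel offset) so the hot loops run in BLAS
without materialising an im2col matrix.  Image tensors are NHWC.
"""

from __future__ import annotations

from typing import Iterable, List, Optional

import numpy as np

_F32 = np.float32

# Large short-lived temporaries dominate the training loop; keeping glibc
# from returning them to the kernel (mmap threshold) avoids re-faulting
# pages on every batch.  Best effort: silently skipped off glibc.
try:  # pragma: no cover - platform dependent
    import ctypes

    ctypes.CDLL("libc.so.6").mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
except Exception:  # noqa: BLE001
    pass


def elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Exponential linear unit: x for x >= 0, alpha*(exp(x)-1) below."""
    x = np.asarray(x)
    return np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


class Param:
    """A trainable array with its gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 same-padding convolution, stride 1, evaluated as nine shifted
    GEMMs (one per kernel offset).

    Each offset's patch block is a nearly contiguous slice of the padded
    input, so the copies feeding BLAS are cheap; training mode caches the
    nine blocks for the weight-gradient GEMMs.  ``skip_input_grad``
    suppresses the dX computation for a first layer, where no upstream
    gradient is needed.
    """

    OFFSETS = [(dy, dx) for dy in range(3) for dx in range(3)]

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 skip_input_grad: bool = False, name: str = "conv") -> None:
        fan_in = 9 * c_in
        # He (fan-in) scaling suits the elu family
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, size=(9, c_in, c_out)), f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self.c_in, self.c_out = c_in, c_out
        self.skip_input_grad = skip_input_grad
        self._buf: dict = {}

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def _buffers(self, B: int, H: int, W: int) -> dict:
        """Scratch arrays reused across steps while the batch shape holds."""
        if self._buf.get("shape") != (B, H, W):
            C, O = self.c_in, self.c_out
            self._buf = {
                "shape": (B, H, W),
                "xp": np.zeros((B, H + 2, W + 2, C), dtype=_F32),
                "patches": [np.empty((B, H, W, C), dtype=_F32)
                            for _ in range(9)],
                "tmp": np.empty((B * H * W, O), dtype=_F32),
                "y": np.empty((B * H * W, O), dtype=_F32),
                "dtmp": np.empty((B * H * W, C), dtype=_F32),
                "dxp": None if self.skip_input_grad else np.empty(
                    (B, H + 2, W + 2, C), dtype=_F32),
            }
        return self._buf

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        buf = self._buffers(B, H, W)
        xp, y, tmp = buf["xp"], buf["y"], buf["tmp"]
        xp[:, 1:-1, 1:-1, :] = x
        y[:] = self.b.value
        w = self.w.value
        for i, (dy, dx) in enumerate(self.OFFSETS):
            patch = buf["patches"][i]
            np.copyto(patch, xp[:, dy:dy + H, dx:dx + W, :])
            flat = patch.reshape(-1, C)
            np.matmul(flat, w[i], out=tmp)
            y += tmp
        self._train_cached = train
        # view into the step-lived scratch buffer; consumed immediately
        return y.reshape(B, H, W, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W = self._buf["shape"]
        C = self.c_in
        buf = self._buf
        g = dout.reshape(-1, self.c_out)
        self.b.grad = g.sum(axis=0)
        w = self.w.value
        dxp = buf["dxp"]
        if dxp is not None:
            dxp[:] = 0.0
        for i, (dy, dx) in enumerate(self.OFFSETS):
            flat = buf["patches"][i].reshape(-1, C)
            self.w.grad[i] = flat.T @ g
            if dxp is not None:
                np.matmul(g, w[i].T, out=buf["dtmp"])
                dxp[:, dy:dy + H, dx:dx + W, :] += buf["dtmp"].reshape(
                    B, H, W, C)
        if dxp is None:
            return np.zeros((B, H, W, C), dtype=_F32)
        return dxp[:, 1:-1, 1:-1, :]


class Elu(Layer):
    """elu(x) = max(x,0) + alpha*expm1(min(x,0)), computed in two in-place
    passes; the derivative is recovered from the output alone."""

    def __init__(self, alpha: float = 1.0) -> None:
        self.alpha = alpha
        self._y: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        t = np.minimum(x, 0.0)
        np.expm1(t, out=t)
        if self.alpha != 1.0:
            t *= self.alpha
        y += t
        y = y.astype(_F32, copy=False)
        self._y = y if train else None
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # elu'(x) = 1 for x >= 0 else elu(x) + alpha
        if self.alpha == 1.0:
            factor = np.minimum(self._y, 0.0)
            factor += 1.0
        else:
            factor = np.where(self._y >= 0, 1.0, self._y + self.alpha)
        self._y = None
        return dout * factor


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped.

    The gradient is routed to the first window cell attaining the maximum
    (raster order), matching a deterministic argmax tie-break.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :2 * H2, :2 * W2, :].reshape(B, H2, 2, W2, 2, C)
        y = np.maximum(
            np.maximum(xc[:, :, 0, :, 0, :], xc[:, :, 0, :, 1, :]),
            np.maximum(xc[:, :, 1, :, 0, :], xc[:, :, 1, :, 1, :]))
        if train:
            self._x, self._y = x, y
        self._in_shape = (B, H, W, C)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._in_shape
        H2, W2 = H // 2, W // 2
        xc = self._x[:, :2 * H2, :2 * W2, :].reshape(B, H2, 2, W2, 2, C)
        dcore = np.zeros((B, H2, 2, W2, 2, C), dtype=_F32)
        taken = np.zeros((B, H2, W2, C), dtype=bool)
        for i in range(2):
            for j in range(2):
                hit = (xc[:, :, i, :, j, :] == self._y) & ~taken
                dcore[:, :, i, :, j, :] = np.where(hit, dout, 0.0)
                taken |= hit
        self._x = self._y = None
        if 2 * H2 == H and 2 * W2 == W:
            return dcore.reshape(B, H, W, C)
        dx = np.zeros((B, H, W, C), dtype=_F32)
        dx[:, :2 * H2, :2 * W2, :] = dcore.reshape(B, 2 * H2, 2 * W2, C)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalisation over all leading axes (NHWC or NC)."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(_F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv, self._axes = xhat.astype(_F32), inv.astype(_F32), axes
        return (self.gamma.value * xhat + self.beta.value).astype(_F32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes, xhat, inv = self._axes, self._xhat, self._inv
        n = dout.size // dout.shape[-1]
        self.gamma.grad = np.sum(dout * xhat, axis=axes)
        self.beta.grad = np.sum(dout, axis=axes)
        g = self.gamma.value * inv
        dx = g * (dout
                  - self.beta.grad / n
                  - xhat * (self.gamma.grad / n))
        self._xhat = None
        return dx.astype(_F32, copy=False)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 name: str = "dense") -> None:
        limit = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.w = Param(rng.uniform(-limit, limit, size=(d_in, d_out)), f"{name}.w")
        self.b = Param(np.zeros(d_out), f"{name}.b")

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad = self._x.T @ dout
        self.b.grad = dout.sum(axis=0)
        self._x = None
        return dout @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; identity outside training mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: Iterable[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
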