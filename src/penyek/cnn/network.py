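"""Minimal NumPy neural-network engine with hand-rolled backprop.

Data layout is (batch, channels, height, width) for rasters.  Conv
layers compute cross-correlation with stride 1 and resolution-preserving
zero padding; on a 1xN input with a kernel whose only non-zero row is
the centre row this equals the full Eq-style reference convolution with
the flipped kernel, cropped to the central N samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray | None = None


def he_uniform(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fan_in: int,
    dtype: np.dtype = np.float32,
) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    trainable: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2D(Layer):
    """2-D cross-correlation, stride 1, 'same' zero padding, square kernel."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        trainable: bool = True,
        dtype: np.dtype = np.float32,
        needs_input_grad: bool = True,
    ):
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.dtype = dtype
        fan_in = in_channels * kernel_size * kernel_size
        self.w = Param(he_uniform(rng, (fan_in, out_channels), fan_in, dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self.trainable = trainable
        # the very first layer of a network can skip computing dL/dx
        self.needs_input_grad = needs_input_grad
        self._col: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        """(b, c, h, w) -> (c*k*k, b*h*w) with 'same' zero padding.

        Built offset-by-offset: each of the k*k window positions is one
        large strided copy, which beats a single 6-D gather.
        """
        b, c, h, w = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        col = np.empty((c, k, k, b, h, w), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                col[:, i, j] = xp[:, :, i : i + h, j : j + w].transpose(1, 0, 2, 3)
        return col.reshape(c * k * k, b * h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"conv layer expects {self.in_channels} input channels, got {c}"
            )
        x = x.astype(self.dtype, copy=False)
        col = self._im2col(x, self.k)
        self._col = col
        self._xshape = x.shape
        out = col.T @ self.w.value + self.b.value  # (b*h*w, F)
        return out.reshape(b, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        b, c, h, w = self._xshape
        grad = np.ascontiguousarray(grad.astype(self.dtype, copy=False))
        gflat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(
            b * h * w, self.out_channels
        )
        self.w.grad = self._col @ gflat
        self.b.grad = gflat.sum(axis=0)
        if not self.needs_input_grad:
            return None
        # dL/dx is the 'same' cross-correlation of grad with the spatially
        # flipped, channel-transposed kernel — same im2col + matmul shape
        k = self.k
        w_spatial = self.w.value.reshape(c, k, k, self.out_channels)
        w_rot = np.ascontiguousarray(
            w_spatial[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)
        ).reshape(self.out_channels * k * k, c)
        gcol = self._im2col(grad, k)
        dx = gcol.T @ w_rot  # (b*h*w, c)
        return dx.reshape(b, h, w, c).transpose(0, 3, 1, 2)

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2D(Layer):
    """Max pooling with square window and stride 2 (floor mode)."""

    def __init__(self, kernel_size: int, stride: int = 2):
        self.k = kernel_size
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h < self.k or w < self.k:
            raise ValueError(
                f"spatial size {h}x{w} smaller than pool window {self.k}"
            )
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))[
            :, :, :: self.stride, :: self.stride
        ]
        b_, c_, ho, wo = win.shape[:4]
        flat = win.reshape(b_, c_, ho, wo, self.k * self.k)
        self._arg = flat.argmax(axis=-1)
        self._xshape = x.shape
        self._oshape = (b_, c_, ho, wo)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, ho, wo = self._oshape
        dx = np.zeros(self._xshape, dtype=grad.dtype)
        bi, ci, oi, oj = np.indices((b, c, ho, wo))
        di, dj = np.divmod(self._arg, self.k)
        ri = oi * self.stride + di
        rj = oj * self.stride + dj
        np.add.at(dx, (bi, ci, ri, rj), grad)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        trainable: bool = True,
        dtype: np.dtype = np.float32,
    ):
        self.w = Param(he_uniform(rng, (in_features, out_features), in_features, dtype))
        self.b = Param(np.zeros(out_features, dtype=dtype))
        self.dtype = dtype
        self.trainable = trainable

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(self.dtype, copy=False)
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(self.dtype, copy=False)
        self.w.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """Sequential stack of layers with softmax/cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy over the batch; fills parameter gradients."""
        logits = self.forward(x)
        probs = softmax(logits)
        n = x.shape[0]
        eps = 1e-12
        loss = -np.log(probs[np.arange(n), y] + eps).mean()
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return float(loss)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self.predict_proba(x)
        return float(-np.log(probs[np.arange(x.shape[0]), y] + 1e-12).mean())

    def trainable_params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            if layer.trainable:
                out.extend(layer.params())
        return out

    def all_params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.all_params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.all_params()
        if len(weights) != len(params):
            raise ValueError(
                f"expected {len(params)} weight arrays, got {len(weights)}"
            )
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {w.shape}")
            p.value = w.copy()


class SGDMomentum:
    def __init__(self, lr: float, momentum: float = 0.9):
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[int, np.ndarray] = {}

    def step(self, params: list[Param]) -> None:
        for p in params:
            if p.grad is None:
                continue
            v = self._vel.get(id(p))
            if v is None:
                v = np.zeros_like(p.value)
            v = self.momentum * v - self.lr * p.grad
            self._vel[id(p)] = v
            p.value = p.value + v


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, params: list[Param]) -> None:
        self._t += 1
        for p in params:
            if p.grad is None:
                continue
            m = self._m.get(id(p), np.zeros_like(p.value))
            v = self._v.get(id(p), np.zeros_like(p.value))
            m = self.beta1 * m + (1 - self.beta1) * p.grad
            v = self.beta2 * v + (1 - self.beta2) * p.grad**2
            self._m[id(p)], self._v[id(p)] = m, v
            mhat = m / (1 - self.beta1**self._t)
            vhat = v / (1 - self.beta2**self._t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {"sgd": SGDMomentum, "adam": Adam}


def numerical_gradient_check(
    net: Network, x: np.ndarray, y: np.ndarray, eps: float = 1e-5
) -> float:
    """Max relative error between analytic and central-difference gradients."""
    net.loss_and_backward(x, y)
    analytic = [p.grad.copy() for p in net.all_params()]
    worst = 0.0
    for p, g in zip(net.all_params(), analytic):
        flat = p.value.ravel()
        it = np.random.default_rng(0).choice(
            flat.size, size=min(20, flat.size), replace=False
        )
        for idx in it:
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = net.loss(x, y)
            flat[idx] = orig - eps
            lm = net.loss(x, y)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num), abs(g.ravel()[idx]), 1e-8)
            worst = max(worst, abs(num - g.ravel()[idx]) / denom)
    return worst
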