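"""Compact NumPy convolutional-network engine.

Implements exactly the building blocks the gesture-recognition networks
need — 3x3 same-padded stride-1 convolution, spatial batch normalisation,
ReLU, 2x2 stride-1 zero-padded average pooling, fully connected layers, a
log-softmax output and the Adam optimiser — with explicit backward passes.
Inputs are small (8x24 single-channel images), so im2col matrix products on
a single CPU are entirely adequate; every layer is gradient-checked against
finite differences in the test suite.

Layout convention: batches are ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "AvgPool2x2",
    "Flatten",
    "Linear",
    "LogSoftmax",
    "Sequential",
    "Adam",
    "nll_loss",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list:
        return []

    def state(self) -> dict:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"p{i}"].copy()


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patch matrix: (N, C, H, W) -> (N, C*9, H*W)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (N, C, H, W, 3, 3) -> (N, C, 3, 3, H, W) -> (N, C*9, H*W)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * 9, h * w
    )


class Conv2d(Layer):
    """3x3 convolution, stride 1, same padding."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (in_ch * 9))
        self.weight = Param(
            (rng.standard_normal((out_ch, in_ch * 9)) * scale).astype(dtype)
        )
        self.bias = Param(np.zeros(out_ch, dtype=dtype))
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._shape = (n, c, h, w)
        self._cols = _im2col(x)
        y = np.matmul(self.weight.value, self._cols)
        y += self.bias.value[:, None]
        return y.reshape(n, self.out_ch, h, w)

    def backward(self, grad):
        n, c, h, w = self._shape
        gf = grad.reshape(n, self.out_ch, h * w)
        self.weight.grad += np.tensordot(gf, self._cols, axes=([0, 2], [0, 2]))
        self.bias.grad += gf.sum(axis=(0, 2))
        # input gradient = correlation of grad with flipped, transposed kernels
        wk = self.weight.value.reshape(self.out_ch, self.in_ch, 3, 3)
        wback = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.in_ch, self.out_ch * 9
        )
        gcols = _im2col(gf.reshape(n, self.out_ch, h, w))
        dx = np.matmul(wback, gcols).reshape(n, self.in_ch, h, w)
        self._cols = None
        return dx


class BatchNorm2d(Layer):
    """Per-feature-map batch normalisation with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(n_ch, dtype=dtype))
        self.beta = Param(np.zeros(n_ch, dtype=dtype))
        self.running_mean = np.zeros(n_ch, dtype=np.float64)
        self.running_var = np.ones(n_ch, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state):
        super().load_state(state)
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._train = train
        self._xhat, self._inv = xhat, inv
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, grad):
        axes = (0, 2, 3)
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.value[None, :, None, None]
        if not self._train:
            return gxhat * inv[None, :, None, None]
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        s1 = gxhat.sum(axis=axes)[None, :, None, None]
        s2 = (gxhat * xhat).sum(axis=axes)[None, :, None, None]
        dx = (gxhat - s1 / n - xhat * s2 / n) * inv[None, :, None, None]
        self._xhat = None
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2x2(Layer):
    """2x2 average pooling with stride 1, zero-padded to keep the size.

    The window anchored at (i, j) averages x[i:i+2, j:j+2] with zeros past
    the bottom/right edge; the divisor is always 4 (zero-padding semantics).
    """

    def forward(self, x, train):
        xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)))
        return 0.25 * (xp[:, :, :-1, :-1] + xp[:, :, 1:, :-1]
                       + xp[:, :, :-1, 1:] + xp[:, :, 1:, 1:])

    def backward(self, grad):
        gp = np.pad(grad, ((0, 0), (0, 0), (1, 0), (1, 0)))
        return 0.25 * (gp[:, :, 1:, 1:] + gp[:, :, :-1, 1:]
                       + gp[:, :, 1:, :-1] + gp[:, :, :-1, :-1])


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Param(
            (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        )
        self.bias = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.value.T
        self._x = None
        return dx


class LogSoftmax(Layer):
    def forward(self, x, train):
        m = x.max(axis=1, keepdims=True)
        z = x - m
        self._logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return self._logp

    def backward(self, grad):
        p = np.exp(self._logp)
        return grad - p * grad.sum(axis=1, keepdims=True)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state(self):
        return {f"l{i}": layer.state() for i, layer in enumerate(self.layers)}

    def load_state(self, state):
        for i, layer in enumerate(self.layers):
            layer.load_state(state[f"l{i}"])

    def zero_grad(self):
        for p in self.params():
            p.grad = np.zeros_like(p.value)

    def astype(self, dtype):
        """Cast all parameters (gradient-check support)."""
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        return self


def nll_loss(logp: np.ndarray, targets: np.ndarray
             ) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient w.r.t. ``logp``."""
    n = logp.shape[0]
    idx = np.arange(n)
    loss = float(-logp[idx, targets].mean())
    grad = np.zeros_like(logp)
    grad[idx, targets] = -1.0 / n
    return loss, grad


class Adam:
    """Adaptive-moment optimiser with bias correction."""

    def __init__(self, params: list, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value = (p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                       ).astype(p.value.dtype)
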