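"""Minimal feed-forward network engine (NumPy, explicit backprop).

Implements exactly the layer inventory the parallel ictal-net needs:
valid 3x3 convolution, the ECA channel gate, ReLU, 2x2 max-pooling,
flatten, dense, softmax, 1-D batch normalization and inverted dropout,
plus SGD and Adam optimizers.  Tensors are channels-last:
feature maps are (batch, height, width, channels), vectors (batch, units).

Everything is float32 and deterministic given the RNGs passed in: weight
initialization draws from the constructor's generator, dropout masks from
the generator handed to ``forward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    def params(self) -> list[Param]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """Non-trainable arrays that still count as model parameters."""
        return []

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv2DValid(Layer):
    """Single-input-channel 3x3 (or kxk) valid convolution with bias."""

    def __init__(self, n_filters: int, kernel_size: int, rng: np.random.Generator):
        k = kernel_size
        fan_in = k * k
        self.kernel = Param(_glorot(rng, (n_filters, k, k), fan_in, n_filters))
        self.bias = Param(np.zeros(n_filters, dtype=DTYPE))
        self.k = k

    def params(self):
        return [self.kernel, self.bias]

    def forward(self, x, training=False, rng=None):
        # x: (B, H, W) -> (B, H-k+1, W-k+1, F)
        self._x = x
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        out = np.tensordot(win, self.kernel.value, axes=([3, 4], [1, 2]))
        out += self.bias.value
        return np.ascontiguousarray(out, dtype=DTYPE)

    def backward(self, grad):
        k = self.k
        win = sliding_window_view(self._x, (k, k), axis=(1, 2))
        self.kernel.grad += np.tensordot(
            grad, win, axes=([0, 1, 2], [0, 1, 2])
        ).transpose(0, 1, 2)
        self.bias.grad += grad.sum(axis=(0, 1, 2))
        # full correlation of grad with the kernel gives dx
        pad = k - 1
        gpad = np.pad(grad, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        gwin = sliding_window_view(gpad, (k, k), axis=(1, 2))  # (B,H,W,F,k,k)
        flipped = self.kernel.value[:, ::-1, ::-1]
        dx = np.tensordot(gwin, flipped, axes=([3, 4, 5], [0, 1, 2]))
        return np.ascontiguousarray(dx, dtype=DTYPE)


class ECAGate(Layer):
    """Efficient channel attention: x * sigmoid(conv1d(GAP(x))).

    Bias-free kernel of odd length k applied across the channel axis with
    zero padding — exactly k parameters.
    """

    def __init__(self, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("ECA kernel size must be odd")
        self.kernel = Param(_glorot(rng, (kernel_size,), kernel_size, 1))
        self.k = kernel_size

    def params(self):
        return [self.kernel]

    @staticmethod
    def _corr(v, w):
        # zero-padded same-length cross-correlation along the last axis
        p = w.size // 2
        vpad = np.pad(v, ((0, 0), (p, p)))
        return sliding_window_view(vpad, w.size, axis=1) @ w

    def forward(self, x, training=False, rng=None):
        self._x = x
        hw = x.shape[1] * x.shape[2]
        self._y = x.mean(axis=(1, 2))  # (B, C)
        self._g = sigmoid(self._corr(self._y, self.kernel.value))
        self._hw = hw
        return x * self._g[:, None, None, :]

    def backward(self, grad):
        g = self._g
        dx = grad * g[:, None, None, :]
        dg = (grad * self._x).sum(axis=(1, 2))
        dz = dg * g * (1.0 - g)
        p = self.k // 2
        ypad = np.pad(self._y, ((0, 0), (p, p)))
        ywin = sliding_window_view(ypad, self.k, axis=1)  # (B, C, k)
        self.kernel.grad += np.einsum("bc,bck->k", dz, ywin).astype(DTYPE)
        dy = self._corr(dz, self.kernel.value[::-1])
        dx += dy[:, None, None, :] / self._hw
        return dx


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns dropped."""

    def forward(self, x, training=False, rng=None):
        b, h, w, c = x.shape
        hh, ww = h // 2, w // 2
        if hh < 1 or ww < 1:
            raise ValueError("feature map too small to pool")
        self._in_shape = x.shape
        xc = x[:, : hh * 2, : ww * 2, :]
        win = xc.reshape(b, hh, 2, ww, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(b, hh, ww, c, 4)
        self._idx = win.argmax(axis=-1)
        return np.ascontiguousarray(win.max(axis=-1))

    def backward(self, grad):
        b, h, w, c = self._in_shape
        hh, ww = h // 2, w // 2
        scattered = np.zeros((b, hh, ww, c, 4), dtype=DTYPE)
        np.put_along_axis(scattered, self._idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        dx[:, : hh * 2, : ww * 2, :] = (
            scattered.reshape(b, hh, ww, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, hh * 2, ww * 2, c)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out, dtype=DTYPE))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Softmax(Layer):
    def forward(self, x, training=False, rng=None):
        self._s = softmax(x)
        return self._s

    def backward(self, grad):
        s = self._s
        return s * (grad - (grad * s).sum(axis=-1, keepdims=True))


class BatchNorm1D(Layer):
    """Batch normalization over (batch, units); 4 parameters per unit
    (gamma, beta trainable; running mean/variance non-trainable)."""

    def __init__(self, n_units: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Param(np.ones(n_units, dtype=DTYPE))
        self.beta = Param(np.zeros(n_units, dtype=DTYPE))
        self.running_mean = np.zeros(n_units, dtype=DTYPE)
        self.running_var = np.ones(n_units, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean[:] = m * self.running_mean + (1 - m) * mu
            self.running_var[:] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        self.gamma.grad += (grad * self._xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        gx = grad * self.gamma.value
        if not self._training:
            return gx * self._inv_std
        n = grad.shape[0]
        xhat = self._xhat
        return (
            self._inv_std
            / n
            * (n * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))
        )


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an RNG")
        self._mask = (rng.random(x.shape) >= self.rate).astype(DTYPE) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def state_arrays(self):
        return [a for l in self.layers for a in l.state_arrays()]

    def forward(self, x, training=False, rng=None):
        for l in self.layers:
            x = l.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[:] = 0


class SGD:
    """Plain stochastic gradient descent (no momentum)."""

    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            p.value -= self.lr * p.grad


class Adam:
    """Adam with the common defaults (b1=0.9, b2=0.999, eps=1e-7)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def make_optimizer(name: str, params: list[Param], lr: float):
    if name == "adam":
        return Adam(params, lr)
    if name == "sgd":
        return SGD(params, lr)
    raise ValueError(f"unknown optimizer {name!r}; choose 'adam' or 'sgd'")
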