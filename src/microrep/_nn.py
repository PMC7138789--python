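"""Minimal seeded neural-network engine (NumPy).

Implements exactly what the autoencoder families and the MLP classifier
need: dense, convolutional and transposed-convolutional layers with
Glorot-uniform initialization, ReLU/sigmoid activations, inverted
dropout, the Adam optimizer, and a reconstruction training loop with
validation-loss early stopping. Everything is driven by
``numpy.random.Generator`` instances so a single integer seed makes a
training run bit-reproducible (single-threaded NumPy ops only).

Array layout for spatial layers is channels-last: (batch, height,
width, channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "ReLU",
    "Sigmoid",
    "Dropout",
    "Reshape",
    "Flatten",
    "Conv2D",
    "ConvTranspose2D",
    "CropPad2D",
    "Sequential",
    "Adam",
    "TrainingLog",
    "TrainingError",
    "train_reconstruction",
]


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Forward/backward protocol; params/grads are parallel lists."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout: active only when training=True."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Reshape(Layer):
    def __init__(self, shape_out):
        self.shape_out = tuple(shape_out)

    def forward(self, x, training=False):
        self._shape_in = x.shape
        return x.reshape((x.shape[0],) + self.shape_out)

    def backward(self, grad):
        return grad.reshape(self._shape_in)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape_in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape_in)


def conv_output_size(size_in: int, filt: int, stride: int) -> int:
    """Valid (no-padding) convolution output arithmetic."""
    return (size_in - filt) // stride + 1


class Conv2D(Layer):
    """Square-kernel valid convolution with stride, channels-last."""

    def __init__(self, c_in, c_out, filt, stride, rng: np.random.Generator):
        self.c_in, self.c_out, self.filt, self.stride = c_in, c_out, filt, stride
        fan_in = c_in * filt * filt
        fan_out = c_out * filt * filt
        self.W = glorot_uniform(rng, (c_in, filt, filt, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        f, s = self.filt, self.stride
        # windows: (N, oh, ow, C, f, f)
        win = sliding_window_view(x, (f, f), axis=(1, 2))[:, ::s, ::s]
        self._x_shape = x.shape
        self._cols = win.reshape(win.shape[:3] + (-1,))
        w2 = self.W.reshape(-1, self.c_out)
        return self._cols @ w2 + self.b

    def backward(self, grad):
        f, s = self.filt, self.stride
        n, oh, ow, _ = grad.shape
        w2 = self.W.reshape(-1, self.c_out)
        self.dW[...] = (
            self._cols.reshape(-1, w2.shape[0]).T @ grad.reshape(-1, self.c_out)
        ).reshape(self.W.shape)
        self.db[...] = grad.sum(axis=(0, 1, 2))
        dcols = (grad @ w2.T).reshape(n, oh, ow, self.c_in, f, f)
        dx = np.zeros(self._x_shape)
        for a in range(f):
            for b in range(f):
                dx[:, a : a + oh * s : s, b : b + ow * s : s, :] += dcols[
                    :, :, :, :, a, b
                ]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ConvTranspose2D(Layer):
    """Transposed (fractionally-strided) convolution, channels-last.

    Output spatial size is (in - 1) * stride + filt per axis.
    """

    def __init__(self, c_in, c_out, filt, stride, rng: np.random.Generator):
        self.c_in, self.c_out, self.filt, self.stride = c_in, c_out, filt, stride
        fan_in = c_in * filt * filt
        fan_out = c_out * filt * filt
        self.W = glorot_uniform(rng, (c_in, filt, filt, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        f, s = self.filt, self.stride
        n, h, w, _ = x.shape
        self._x = x
        oh, ow = (h - 1) * s + f, (w - 1) * s + f
        t = (x.reshape(-1, self.c_in) @ self.W.reshape(self.c_in, -1)).reshape(
            n, h, w, f, f, self.c_out
        )
        out = np.zeros((n, oh, ow, self.c_out))
        for a in range(f):
            for b in range(f):
                out[:, a : a + h * s : s, b : b + w * s : s, :] += t[:, :, :, a, b, :]
        return out + self.b

    def backward(self, grad):
        f, s = self.filt, self.stride
        n, h, w, _ = self._x.shape
        gt = np.empty((n, h, w, f, f, self.c_out))
        for a in range(f):
            for b in range(f):
                gt[:, :, :, a, b, :] = grad[:, a : a + h * s : s, b : b + w * s : s, :]
        g2 = gt.reshape(n * h * w, -1)
        x2 = self._x.reshape(n * h * w, self.c_in)
        self.dW[...] = (x2.T @ g2).reshape(self.W.shape)
        self.db[...] = grad.sum(axis=(0, 1, 2))
        return (g2 @ self.W.reshape(self.c_in, -1).T).reshape(self._x.shape)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class CropPad2D(Layer):
    """Center-free crop/zero-pad of the spatial axes to a target square size."""

    def __init__(self, target: int):
        self.target = target

    def forward(self, x, training=False):
        self._shape_in = x.shape
        n, h, w, c = x.shape
        d = self.target
        out = np.zeros((n, d, d, c))
        hh, ww = min(h, d), min(w, d)
        out[:, :hh, :ww, :] = x[:, :hh, :ww, :]
        return out

    def backward(self, grad):
        n, h, w, c = self._shape_in
        d = self.target
        out = np.zeros(self._shape_in)
        hh, ww = min(h, d), min(w, d)
        out[:, :hh, :ww, :] = grad[:, :hh, :ww, :]
        return out


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


class Adam:
    """Adam with the conventional defaults used throughout the package
    (learning rate 0.001, epsilon 1e-07, betas 0.9/0.999)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


@dataclass
class TrainingLog:
    """Per-epoch training/validation reconstruction losses."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        # earliest epoch attaining the minimum validation loss
        arr = np.asarray(self.val_loss)
        return int(np.argmin(arr))

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


def get_weights(model) -> list:
    return [p.copy() for p in model.params()]


def set_weights(model, weights) -> None:
    for p, w in zip(model.params(), weights):
        p[...] = w


def train_reconstruction(
    model,
    x_train: np.ndarray,
    x_val: np.ndarray,
    seed: "int | np.random.Generator",
    *,
    batch_size: int = 32,
    max_epochs: int = 2000,
    patience: int = 20,
    lr: float = 1e-3,
    adam_eps: float = 1e-7,
) -> TrainingLog:
    """Minimize reconstruction loss with Adam and early stopping.

    ``model`` must implement ``training_step(batch) -> loss`` (forward,
    loss, backward into its grads) and ``evaluate(x) -> loss``. Training
    stops once the validation loss has not improved for ``patience``
    consecutive epochs; the weights of the earliest epoch attaining the
    minimum validation loss are restored before returning.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=lr, eps=adam_eps)
    log = TrainingLog()
    n = x_train.shape[0]
    best_val = np.inf
    best_weights = get_weights(model)
    best_epoch = -1

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            batch = x_train[order[start : start + batch_size]]
            loss = model.training_step(batch)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.step(model.grads())
            epoch_loss += loss * batch.shape[0]
        log.train_loss.append(epoch_loss / n)
        val = model.evaluate(x_val)
        if not np.isfinite(val):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        log.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_epoch = epoch
            best_weights = get_weights(model)
        elif epoch - best_epoch >= patience:
            break
    set_weights(model, best_weights)
    return log
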