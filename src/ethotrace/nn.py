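"""A compact dependency-free convolutional network for binary behaviors.

The recognizer follows a fixed recipe: stacked 3×3 convolution blocks with
Elu activations and batch normalization applied before each 2×2 max-pooling,
a dense head with dropout after the inner dense layer, a single sigmoid
output, binary cross-entropy loss, and stochastic gradient descent with
learning rate 1e-4 and momentum 0.9.  Everything (initialisation, shuffling,
dropout) is driven by one seed, so training is bit-reproducible on a given
machine.  Arrays are NCHW float64; inputs are expected in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClassifierSpec", "BehaviorClassifier", "TrainHistory"]


@dataclass
class ClassifierSpec:
    """Architecture and optimizer settings of the behavior recognizer."""

    input_size: tuple[int, int] = (64, 64)
    conv_channels: tuple[int, ...] = (8, 16, 32)
    dense_units: tuple[int, ...] = (64,)
    dropout: float = 0.5
    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 8

    def __post_init__(self):
        h, w = self.input_size
        if h % (2 ** len(self.conv_channels)) or w % (2 ** len(self.conv_channels)):
            raise ValueError("input size must be divisible by 2**n_blocks")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) → (N, C·k·k, H·W) patch matrix with 'same' zero padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c * k * k, h * w), dtype=x.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            patch = xp[:, :, di:di + h, dj:dj + w]
            cols[:, idx * c:(idx + 1) * c, :] = patch.reshape(n, c, h * w)
            idx += 1
    return cols


def _col2im(cols: np.ndarray, shape: tuple, k: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    p = k // 2
    out = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            out[:, :, di:di + h, dj:dj + w] += cols[:, idx * c:(idx + 1) * c, :].reshape(n, c, h, w)
            idx += 1
    return out[:, :, p:p + h, p:p + w]


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, y + 1.0)


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.k = k
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in))
        self.b = np.zeros(c_out)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k)
        n, _, hw = self.cols.shape
        h, w = self.x_shape[2:]
        out = np.einsum("of,nfp->nop", self.W, self.cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, co, h, w = grad.shape
        g = grad.reshape(n, co, h * w)
        self.dW = np.einsum("nop,nfp->of", g, self.cols) / n
        self.db = g.sum(axis=(0, 2)) / n
        dcols = np.einsum("of,nop->nfp", self.W, g)
        return _col2im(dcols, self.x_shape, self.k)

    def step(self, lr: float, mu: float) -> None:
        self.vW = mu * self.vW - lr * self.dW
        self.vb = mu * self.vb - lr * self.db
        self.W += self.vW
        self.b += self.vb


class _BatchNorm:
    """Per-channel batch normalization (NCHW or NF)."""

    def __init__(self, c: int, eps: float = 1e-5, track_momentum: float = 0.9):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.vg = np.zeros(c)
        self.vb = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.eps = eps
        self.mom = track_momentum

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.mom * self.run_mean + (1 - self.mom) * mean
            self.run_var = self.mom * self.run_var + (1 - self.mom) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.x = x
        self.mean, self.var, self.axes, self.shape = mean, var, axes, shape
        self.xhat = (x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + self.eps)
        return self.gamma.reshape(shape) * self.xhat + self.beta.reshape(shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        m = self.x.size / self.gamma.size
        shape = self.shape
        self.dgamma = (grad * self.xhat).sum(axis=self.axes) / self.x.shape[0]
        self.dbeta = grad.sum(axis=self.axes) / self.x.shape[0]
        g = grad * self.gamma.reshape(shape)
        inv = 1.0 / np.sqrt(self.var.reshape(shape) + self.eps)
        dxhat_sum = g.sum(axis=self.axes).reshape(shape)
        dxhat_xhat = (g * self.xhat).sum(axis=self.axes).reshape(shape)
        return inv / m * (m * g - dxhat_sum - self.xhat * dxhat_xhat)

    def step(self, lr: float, mu: float) -> None:
        self.vg = mu * self.vg - lr * self.dgamma
        self.vb = mu * self.vb - lr * self.dbeta
        self.gamma += self.vg
        self.beta += self.vb


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        self.mask = r == out[:, :, :, None, :, None]
        self.in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad[:, :, :, None, :, None] * self.mask
        n, c, h, w = self.in_shape
        return g.reshape(n, c, h, w)

    def step(self, lr, mu):  # stateless
        pass


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = len(self.x)
        self.dW = self.x.T @ grad / n
        self.db = grad.sum(axis=0) / n
        return grad @ self.W.T

    def step(self, lr: float, mu: float) -> None:
        self.vW = mu * self.vW - lr * self.dW
        self.vb = mu * self.vb - lr * self.db
        self.W += self.vW
        self.b += self.vb


class BehaviorClassifier:
    """Binary behavior recognizer with the fixed conv/dense recipe."""

    def __init__(self, spec: ClassifierSpec | None = None, seed: int = 0):
        self.spec = spec or ClassifierSpec()
        self.rng = np.random.default_rng(seed)
        s = self.spec
        self.blocks = []
        c_in = 1
        for c_out in s.conv_channels:
            conv = _Conv(c_in, c_out, self.rng)
            bn = _BatchNorm(c_out)
            pool = _MaxPool2()
            self.blocks.append((conv, bn, pool))
            c_in = c_out
        h, w = s.input_size
        feat = c_in * (h // 2 ** len(s.conv_channels)) * (w // 2 ** len(s.conv_channels))
        self.dense = []
        n_in = feat
        for units in s.dense_units:
            self.dense.append(_Dense(n_in, units, self.rng))
            n_in = units
        self.out = _Dense(n_in, 1, self.rng)

    # -- forward / backward ----------------------------------------------
    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._cache = []
        h = x
        for conv, bn, pool in self.blocks:
            z = conv.forward(h)
            a = _elu(z)
            self._cache.append((z, a))
            h = pool.forward(bn.forward(a, train))
        n = h.shape[0]
        h = h.reshape(n, -1)
        self._flat_shape = None
        self._dense_cache = []
        for d in self.dense:
            z = d.forward(h)
            a = _elu(z)
            mask = None
            if train and self.spec.dropout > 0:
                mask = (self.rng.uniform(size=a.shape) >= self.spec.dropout) / (1 - self.spec.dropout)
                a = a * mask
            self._dense_cache.append((z, a, mask))
            h = a
        logit = self.out.forward(h)[:, 0]
        return logit

    def _backward(self, dlogit: np.ndarray) -> None:
        g = self.out.backward(dlogit[:, None])
        for d, (z, a, mask) in zip(reversed(self.dense), reversed(self._dense_cache)):
            if mask is not None:
                g = g * mask
            g = g * _elu_grad(z, _elu(z))
            g = d.backward(g)
        n = g.shape[0]
        last_pool_out = None
        # reshape back to the conv feature map
        conv, bn, pool = self.blocks[-1]
        h, w = self.spec.input_size
        ds = 2 ** len(self.blocks)
        g = g.reshape(n, self.spec.conv_channels[-1], h // ds, w // ds)
        for (conv, bn, pool), (z, a) in zip(reversed(self.blocks), reversed(self._cache)):
            g = pool.backward(g)
            g = bn.backward(g)
            g = g * _elu_grad(z, a)
            g = conv.backward(g)

    def _step(self) -> None:
        lr, mu = self.spec.learning_rate, self.spec.momentum
        for conv, bn, pool in self.blocks:
            conv.step(lr, mu)
            bn.step(lr, mu)
        for d in self.dense:
            d.step(lr, mu)
        self.out.step(lr, mu)

    # -- public API -------------------------------------------------------
    @staticmethod
    def _as_nchw(crops: np.ndarray) -> np.ndarray:
        x = np.asarray(crops, dtype=float)
        if x.ndim == 3:
            x = x[:, None, :, :]
        return x

    def predict_proba(self, crops: np.ndarray) -> np.ndarray:
        """Sigmoid output probability per crop (inference mode)."""
        x = self._as_nchw(crops)
        logit = self._forward(x, train=False)
        return 1.0 / (1.0 + np.exp(-logit))

    def predict(self, crops: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(crops) >= threshold).astype(int)

    def fit(self, crops: np.ndarray, labels: np.ndarray, epochs: int = 100,
            val: tuple[np.ndarray, np.ndarray] | None = None) -> TrainHistory:
        """Minibatch SGD-with-momentum training on binary cross-entropy."""
        x = self._as_nchw(crops)
        y = np.asarray(labels, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary")
        hist = TrainHistory()
        n = len(x)
        bs = min(self.spec.batch_size, n)
        for _epoch in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                logit = self._forward(x[idx], train=True)
                p = 1.0 / (1.0 + np.exp(-logit))
                eps = 1e-12
                losses.append(float(-(y[idx] * np.log(p + eps)
                                      + (1 - y[idx]) * np.log(1 - p + eps)).mean()))
                self._backward(p - y[idx])
                self._step()
            hist.loss.append(float(np.mean(losses)))
            hist.accuracy.append(float((self.predict(x[:, 0]) == y).mean()))
            if val is not None:
                vx, vy = val
                vp = self.predict_proba(vx)
                eps = 1e-12
                hist.val_loss.append(float(-(vy * np.log(vp + eps)
                                             + (1 - vy) * np.log(1 - vp + eps)).mean()))
                hist.val_accuracy.append(float(((vp >= 0.5).astype(int) == vy).mean()))
        return hist
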