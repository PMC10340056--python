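"""Minimal trainable layer library (numpy, NCHW batches).

Every layer implements ``forward(x, train)`` and ``backward(dy)`` and
exposes its parameters as :class:`Param` objects carrying value and
gradient; :class:`Adam` updates them. Backward passes are validated
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .ops import shuffle_permutation

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "ChannelShuffle",
    "ECALayer",
    "ReLU",
    "MaxPool2",
    "BatchNorm2d",
    "Dropout",
    "Flatten",
    "ToSequence",
    "Dense",
    "LSTM",
    "Sequential",
    "Adam",
    "softmax",
    "smoothed_cross_entropy",
]

_DT = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DT)


class Conv2d(Layer):
    """2-D convolution via im2col; stride 1, configurable zero padding."""

    def __init__(self, cin: int, cout: int, k: int, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2 if pad is None else pad
        self.w = Param(_he_init(rng, (cout, cin * k * k), cin * k * k))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_DT)
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        if k == 1 and p == 0:
            # pointwise: plain channel-mixing matmul
            self._x_shape, self._cols = x.shape, x.transpose(0, 2, 3, 1).reshape(-1, c)
            y = self._cols @ self.w.value.T + self.b.value
            return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh, ow = h + 2 * p - k + 1, w + 2 * p - k + 1
        if oh < 1 or ow < 1:
            raise ValueError("kernel larger than (padded) input")
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        self._x_shape, self._cols, self._out_hw = x.shape, cols, (oh, ow)
        y = cols @ self.w.value.T + self.b.value
        return y.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w = self._x_shape
        k, p = self.k, self.pad
        if k == 1 and p == 0:
            dy_flat = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
            self.w.grad += dy_flat.T @ self._cols
            self.b.grad += dy_flat.sum(0)
            dx = (dy_flat @ self.w.value).reshape(n, h, w, c).transpose(0, 3, 1, 2)
            return np.ascontiguousarray(dx)
        oh, ow = self._out_hw
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.cout)
        self.w.grad += dy_flat.T @ self._cols
        self.b.grad += dy_flat.sum(0)
        dcols = (dy_flat @ self.w.value).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=_DT)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class DepthwiseConv2d(Layer):
    """Per-channel convolution (no cross-channel mixing); stride 1."""

    def __init__(self, channels: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.channels, self.k = channels, k
        self.pad = k // 2 if pad is None else pad
        self.w = Param(_he_init(rng, (channels, k, k), k * k))
        self.b = Param(np.zeros(channels))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_DT)
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh, ow = h + 2 * p - k + 1, w + 2 * p - k + 1
        self._xp, self._x_shape = xp, x.shape
        # shift-and-add: k*k fully vectorized multiply-accumulates
        y = np.zeros((n, c, oh, ow), dtype=_DT)
        for i in range(k):
            for j in range(k):
                y += xp[:, :, i:i + oh, j:j + ow] * self.w.value[None, :, i, j, None, None]
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        n, c, h, w = self._x_shape
        k, p = self.k, self.pad
        oh, ow = h + 2 * p - k + 1, w + 2 * p - k + 1
        xp = self._xp
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                self.w.grad[:, i, j] += (dy * xp[:, :, i:i + oh, j:j + ow]).sum(axis=(0, 2, 3))
                dxp[:, :, i:i + oh, j:j + ow] += dy * self.w.value[None, :, i, j, None, None]
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ChannelShuffle(Layer):
    """Fixed channel permutation interleaving the groups."""

    def __init__(self, groups: int):
        self.groups = groups
        self._perm = None

    def forward(self, x, train=False):
        if self._perm is None or self._perm.size != x.shape[1]:
            self._perm = shuffle_permutation(x.shape[1], self.groups)
            self._inv = np.argsort(self._perm)
        return x[:, self._perm]

    def backward(self, dy):
        return dy[:, self._inv]


class ECALayer(Layer):
    """Efficient channel attention: GAP -> 1-D conv over channels -> sigmoid
    -> per-channel rescale. The only parameter is the length-k conv kernel."""

    def __init__(self, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 == 0:
            raise ValueError("ECA kernel length must be odd")
        rng = rng or np.random.default_rng()
        self.k = k
        self.w = Param(rng.standard_normal(k) * 0.1)

    def params(self):
        return [self.w]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        pad = self.k // 2
        favg = x.mean(axis=(2, 3))
        win = np.lib.stride_tricks.sliding_window_view(np.pad(favg, ((0, 0), (pad, pad))), self.k, axis=1)
        s = win @ self.w.value
        a = _sig(s)
        self._x, self._win, self._a = x, win, a
        return x * a[:, :, None, None].astype(_DT)

    def backward(self, dy):
        n, c, h, w = self._x.shape
        pad = self.k // 2
        a = self._a
        dx = dy * a[:, :, None, None].astype(_DT)
        da = (dy * self._x).sum(axis=(2, 3))
        ds = da * a * (1.0 - a)
        self.w.grad += np.einsum("nck,nc->k", self._win, ds).astype(_DT)
        # transpose of same-padded cross-correlation: correlate with the
        # reversed kernel
        dwin = np.lib.stride_tricks.sliding_window_view(np.pad(ds, ((0, 0), (pad, pad))), self.k, axis=1)
        dfavg = dwin @ self.w.value[::-1]
        dx += (dfavg / (h * w))[:, :, None, None].astype(_DT)
        return dx


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (even input sides required)."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("input sides must be even for 2x2/2 pooling")
        patches = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        patches = patches.reshape(n, c, h // 2, w // 2, 4)
        self._idx = patches.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(patches, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._x_shape
        dpatch = np.zeros((n, c, h // 2, w // 2, 4), dtype=_DT)
        np.put_along_axis(dpatch, self._idx[..., None], dy[..., None], axis=-1)
        dpatch = dpatch.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dpatch.reshape(n, c, h, w)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        self._train = train
        return (self.gamma.value[None, :, None, None] * self._xhat
                + self.beta.value[None, :, None, None]).astype(_DT)

    def backward(self, dy):
        xhat, istd = self._xhat, self._istd
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        if not self._train:
            return (dxhat * istd[None, :, None, None]).astype(_DT)
        n_eff = dy.shape[0] * dy.shape[2] * dy.shape[3]
        term = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return (term * istd[None, :, None, None]).astype(_DT)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DT) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ToSequence(Layer):
    """Reinterpret a feature map as a width-axis sequence.

    (N, C, H, W) -> (N, W, C*H): each image column becomes one timestep
    whose feature vector stacks channels and rows.
    """

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        self._shape = x.shape
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2).reshape(n, w, c * h))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.ascontiguousarray(dy.reshape(n, w, c, h).transpose(0, 2, 3, 1))


class Dense(Layer):
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Param(_he_init(rng, (fan_in, fan_out), fan_in))
        self.b = Param(np.zeros(fan_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(0)
        return dy @ self.w.value.T


class LSTM(Layer):
    """Single-layer LSTM consuming (N, T, F); emits the final hidden state.

    Gate order in the stacked weight matrices is input, forget, cell, output;
    the forget-gate bias starts at 1 so early training does not wash out the
    cell state.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.input_size, self.hidden_size = input_size, hidden_size
        scale = 1.0 / np.sqrt(input_size + hidden_size)
        self.wx = Param(rng.standard_normal((input_size, 4 * hidden_size)) * scale)
        self.wh = Param(rng.standard_normal((hidden_size, 4 * hidden_size)) * scale)
        b = np.zeros(4 * hidden_size, dtype=_DT)
        b[hidden_size:2 * hidden_size] = 1.0
        self.b = Param(b)

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=_DT)
        n, t, f = x.shape
        hs = self.hidden_size
        h = np.zeros((n, hs), dtype=_DT)
        c = np.zeros((n, hs), dtype=_DT)
        self._x = x
        self._cache = []
        for step in range(t):
            z = x[:, step] @ self.wx.value + h @ self.wh.value + self.b.value
            i = _sig(z[:, :hs])
            fg = _sig(z[:, hs:2 * hs])
            g = np.tanh(z[:, 2 * hs:3 * hs])
            o = _sig(z[:, 3 * hs:])
            c_prev = c
            c = fg * c_prev + i * g
            tc = np.tanh(c)
            self._cache.append((h.copy(), c_prev, i, fg, g, o, tc))
            h = o * tc
        return h

    def backward(self, dy):
        x = self._x
        n, t, f = x.shape
        hs = self.hidden_size
        dh = np.asarray(dy, dtype=_DT)
        dc = np.zeros_like(dh)
        dx = np.zeros_like(x)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, fg, g, o, tc = self._cache[step]
            do = dh * tc
            dct = dh * o * (1.0 - tc * tc) + dc
            di = dct * g
            dfg = dct * c_prev
            dg = dct * i
            dc = dct * fg
            dz = np.concatenate(
                [di * i * (1 - i), dfg * fg * (1 - fg),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            self.wx.grad += x[:, step].T @ dz
            self.wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(0)
            dx[:, step] = dz @ self.wx.value.T
            dh = dz @ self.wh.value.T
        return dx


def _sig(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def smoothed_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, epsilon: float = 0.0
) -> tuple[float, np.ndarray]:
    """Label-smoothing cross-entropy; returns (mean loss, dlogits).

    The target distribution puts ``1 - epsilon`` on the true class and
    spreads ``epsilon`` uniformly over all classes; ``epsilon = 0`` is
    plain cross-entropy.
    """
    n, k = logits.shape
    p = softmax(logits.astype(np.float64))
    q = np.full((n, k), epsilon / k)
    q[np.arange(n), labels] += 1.0 - epsilon
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(q * logp).sum() / n)
    dlogits = ((p - q) / n).astype(_DT)
    return loss, dlogits


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                  + self.weight_decay * p.value)
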