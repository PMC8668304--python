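"""Layer implementations (NCHW layout).

Each layer exposes ``forward(x, train)`` / ``backward(dy)`` and keeps its
parameters and gradients in the ``params`` / ``grads`` dicts.  Setting
``layer.trainable = False`` freezes it: the optimizer skips its parameters
entirely, so frozen weights are bit-identical before and after training.
"""

from __future__ import annotations

import numpy as np

from ..errors import SizeError


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization on [-limit, limit]."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> columns (N, C*kh*kw, OH*OW) plus output shape."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, kh, kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col`: scatter-add columns back onto the image."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    d = dcols.reshape(n, c, kh, kw, oh, ow)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Layer:
    trainable = True

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution (cross-correlation) with symmetric zero padding."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=1, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        fan_out = c_out * kernel * kernel
        self.params["W"] = glorot_uniform(rng, (c_out, fan_in), fan_in, fan_out)
        self.params["b"] = np.zeros(c_out)
        self._x = None

    def forward(self, x, train=True):
        self._x = x
        n = x.shape[0]
        cols, oh, ow = _im2col(x, self.k, self.k, self.stride, self.pad)
        # one big GEMM: (c_out, K) @ (K, N*L)
        flat = cols.transpose(1, 0, 2).reshape(cols.shape[1], -1)
        y = (self.params["W"] @ flat).reshape(self.c_out, n, oh * ow).transpose(1, 0, 2)
        y = y + self.params["b"][:, None]
        return np.ascontiguousarray(y.reshape(n, self.c_out, oh, ow))

    def backward(self, dy):
        x = self._x
        n = x.shape[0]
        dyf = dy.reshape(n, self.c_out, -1)
        dflat = dyf.transpose(1, 0, 2).reshape(self.c_out, -1)  # (c_out, N*L)
        cols, _, _ = _im2col(x, self.k, self.k, self.stride, self.pad)
        flat = cols.transpose(1, 0, 2).reshape(cols.shape[1], -1)  # (K, N*L)
        self.grads["W"] = dflat @ flat.T
        self.grads["b"] = dyf.sum(axis=(0, 2))
        dcols_flat = self.params["W"].T @ dflat  # (K, N*L)
        dcols = dcols_flat.reshape(cols.shape[1], n, -1).transpose(1, 0, 2)
        return _col2im(np.ascontiguousarray(dcols), x.shape, self.k, self.k, self.stride, self.pad)


class ConvTranspose2D(Layer):
    """Stride-2 transposed convolution with a 2x2 kernel (exact x2 upsample)."""

    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        fan_in, fan_out = c_in * 4, c_out * 4
        self.params["W"] = glorot_uniform(rng, (c_in, c_out, 2, 2), fan_in, fan_out)
        self.params["b"] = np.zeros(c_out)
        self._x = None

    def forward(self, x, train=True):
        self._x = x
        n, _, h, w = x.shape
        # tensordot over c_in -> (n, h, w, o, k, l), then interleave k/l
        y = np.tensordot(x, self.params["W"], axes=([1], [0]))
        y = y.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.c_out, 2 * h, 2 * w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        x = self._x
        n, _, h, w = x.shape
        dy6 = dy.reshape(n, self.c_out, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        # dy6: (n, h, w, o, k, l)
        self.grads["W"] = np.tensordot(x, dy6, axes=([0, 2, 3], [0, 1, 2]))
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dy6, self.params["W"], axes=([3, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics at inference."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
            return self.params["gamma"][None, :, None, None] * self._xhat + self.params["beta"][
                None, :, None, None
            ]
        std = np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) / std[None, :, None, None]
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, dy):
        xhat, std = self._xhat, self._std
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        )
        return term / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2D(Layer):
    """Max pooling; default 2x2 window with stride 2."""

    def __init__(self, kernel=2, stride=2):
        super().__init__()
        self.k, self.stride = kernel, stride

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        if (h - k) % s or (w - k) % s:
            raise SizeError(f"pooling window {k}/stride {s} does not tile {h}x{w}")
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s].reshape(n, c, (h - k) // s + 1, (w - k) // s + 1, k * k)
        self._x_shape = x.shape
        self._idx = win.argmax(axis=-1)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._x_shape
        k, s = self.k, self.stride
        oh, ow = dy.shape[2], dy.shape[3]
        dx = np.zeros((n, c, h, w), dtype=dy.dtype)
        for p in range(k * k):
            i, j = divmod(p, k)
            sel = self._idx == p
            view = dx[:, :, i : i + s * oh : s, j : j + s * ow : s]
            view += np.where(sel, dy, 0.0)
        return dx


class GlobalAvgPool2D(Layer):
    def forward(self, x, train=True):
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._x_shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._x_shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params["W"] = glorot_uniform(rng, (d_in, d_out), d_in, d_out)
        self.params["b"] = np.zeros(d_out)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout with its own seeded generator (active only in train)."""

    def __init__(self, p=0.5, seed=0):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x, train=True):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Concat(Layer):
    """Parallel branches applied to one input; outputs concatenated on the
    channel axis (the inception pattern).  Each branch is a Sequential."""

    def __init__(self, branches):
        super().__init__()
        self.branches = branches

    def forward(self, x, train=True):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._channels = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dx = None
        start = 0
        for b, c in zip(self.branches, self._channels):
            d = b.backward(dy[:, start : start + c])
            dx = d if dx is None else dx + d
            start += c
        return dx

    def iter_layers(self):
        for b in self.branches:
            yield from b.iter_layers()


class Sequential:
    """Ordered layer container with reverse-order backprop."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Concat):
                yield layer
                yield from layer.iter_layers()
            elif isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer

    def trainable_parameters(self):
        """Stable list of (layer, param_name) for every unfrozen parameter."""
        out = []
        for layer in self.iter_layers():
            if getattr(layer, "trainable", True):
                for name in layer.params:
                    out.append((layer, name))
        return out

    def state_dict(self):
        state = {}
        for i, layer in enumerate(self.iter_layers()):
            for name, value in layer.params.items():
                state[f"{i}.{name}"] = value
            if isinstance(layer, BatchNorm2D):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state):
        for i, layer in enumerate(self.iter_layers()):
            for name in layer.params:
                layer.params[name] = np.array(state[f"{i}.{name}"])
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = np.array(state[f"{i}.running_mean"])
                layer.running_var = np.array(state[f"{i}.running_var"])
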