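"""Minimal conv-net building blocks on numpy.

Implements exactly what the atrous segmentation network needs: 2-D
convolution with stride and dilation (im2col), ReLU, global average
pooling, bilinear upsampling, channel concatenation, a sigmoid
binary-cross-entropy loss, and an Adam update.  Layers cache their
forward inputs and expose ``backward`` returning the gradient w.r.t.
their input; parameters and gradients are plain arrays.
"""

from __future__ import annotations

import numpy as np

_INDEX_CACHE: dict = {}


def _conv_indices(h, w, k, stride, dilation, pad):
    key = (h, w, k, stride, dilation, pad)
    hit = _INDEX_CACHE.get(key)
    if hit is not None:
        return hit
    oh = (h + 2 * pad - dilation * (k - 1) - 1) // stride + 1
    ow = (w + 2 * pad - dilation * (k - 1) - 1) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("convolution output would be empty")
    ki, kj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    oi, oj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
    ii = (ki.ravel() * dilation)[:, None] + (oi.ravel() * stride)[None, :]
    jj = (kj.ravel() * dilation)[:, None] + (oj.ravel() * stride)[None, :]
    _INDEX_CACHE[key] = (oh, ow, ii, jj)
    return oh, ow, ii, jj


class Conv2d:
    """Same-padded (by default) convolution with stride and dilation."""

    def __init__(self, cin, cout, k=3, stride=1, dilation=1, pad=None, rng=None):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation = stride, dilation
        self.pad = dilation * (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x):
        n, c, h, w = x.shape
        oh, ow, ii, jj = _conv_indices(h, w, self.k, self.stride, self.dilation, self.pad)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = xp[:, :, ii, jj].reshape(n, c * self.k * self.k, -1)
        wm = self.W.reshape(self.cout, -1)
        out = np.matmul(wm, cols).reshape(n, self.cout, oh, ow)
        out += self.b[None, :, None, None]
        self._cache = (x.shape, xp.shape, cols, ii, jj)
        return out

    def backward(self, g):
        (n, c, h, w), xp_shape, cols, ii, jj = self._cache
        gm = g.reshape(n, self.cout, -1)
        self.gb += g.sum(axis=(0, 2, 3))
        self.gW += np.einsum("nol,nkl->ok", gm, cols).reshape(self.W.shape)
        dcols = np.matmul(self.W.reshape(self.cout, -1).T, gm)
        dcols = dcols.reshape(n, c, self.k * self.k, -1)
        gxp = np.zeros(xp_shape)
        np.add.at(
            gxp,
            (
                np.arange(n)[:, None, None, None],
                np.arange(c)[None, :, None, None],
                ii[None, None],
                jj[None, None],
            ),
            dcols,
        )
        p = self.pad
        return gxp[:, :, p : p + h, p : p + w]


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return g * self._mask


class GlobalAvgPool:
    """Mean over the spatial grid, broadcast back to the input shape."""

    def __init__(self):
        self._shape = None

    def parameters(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return np.broadcast_to(x.mean(axis=(2, 3), keepdims=True), x.shape).copy()

    def backward(self, g):
        n, c, h, w = self._shape
        return np.broadcast_to(g.sum(axis=(2, 3), keepdims=True) / (h * w), self._shape).copy()


def _interp_matrix(n_out, n_in, factor):
    """Row-stochastic bilinear interpolation matrix (half-pixel centres)."""
    m = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


class BilinearUpsample:
    def __init__(self, factor):
        self.factor = factor
        self._mats = None

    def parameters(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        mr = _interp_matrix(h * self.factor, h, self.factor)
        mc = _interp_matrix(w * self.factor, w, self.factor)
        self._mats = (mr, mc)
        return np.einsum("ih,nchw,jw->ncij", mr, x, mc, optimize=True)

    def backward(self, g):
        mr, mc = self._mats
        return np.einsum("ih,ncij,jw->nchw", mr, g, mc, optimize=True)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class ResidualBlock:
    """Two 3x3 convolutions with a (projected) identity shortcut."""

    def __init__(self, cin, cout, stride=1, dilation=1, rng=None):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, dilation=dilation, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, dilation=dilation, rng=rng)
        self.proj = (
            Conv2d(cin, cout, 1, stride=stride, rng=rng)
            if (cin != cout or stride != 1)
            else None
        )
        self.relu_out = ReLU()

    def parameters(self):
        params = self.conv1.parameters() + self.conv2.parameters()
        if self.proj is not None:
            params += self.proj.parameters()
        return params

    def forward(self, x):
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu_out.forward(main + skip)

    def backward(self, g):
        g = self.relu_out.backward(g)
        g_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        g_skip = self.proj.backward(g) if self.proj is not None else g
        return g_main + g_skip


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, y):
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad


class Adam:
    """Adam update over (param, grad) pairs; grads are zeroed after a step."""

    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            g[...] = 0.0
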