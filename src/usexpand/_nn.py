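"""Minimal numpy neural-network core.

Layers store no activations: ``forward`` returns ``(y, cache)`` and
``backward(dy, cache)`` returns ``dx`` while accumulating parameter
gradients. This functional style lets one network be applied several
times inside a single training step (as cycle-consistent training
requires) without clobbering intermediate state.

Array layout is NCHW throughout; all randomness flows through an
explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Sequential", "Residual",
    "Conv2d", "Dense", "Flatten", "MaxPool2", "UpsampleNearest2",
    "ReLU", "LeakyReLU", "Tanh", "Dropout", "InstanceNorm2d",
    "Adam", "softmax", "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, rng=None, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col machinery


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, out_h, out_w); cols has shape (N*oh*ow, C*kh*kw)."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(view.transpose(0, 4, 5, 1, 2, 3))
    return cols.reshape(n * oh * ow, c * kh * kw), oh, ow


def _col2im(dcols, x_shape, kh, kw, stride, pad, oh, ow):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, cin, cout, k, stride=1, pad=None, rng=None, gain=np.sqrt(2.0)):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        std = gain / np.sqrt(cin * k * k)
        self.w = Param(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, rng=None, train=False):
        cols, oh, ow = _im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = self.w.value.reshape(self.cout, -1)
        y = cols @ wmat.T + self.b.value
        y = y.reshape(x.shape[0], oh, ow, self.cout).transpose(0, 3, 1, 2)
        return y, (cols, x.shape, oh, ow)

    def backward(self, dy, cache):
        cols, x_shape, oh, ow = cache
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.w.grad += (dyf.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.w.value.reshape(self.cout, -1)
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad, oh, ow)


class Dense(Layer):
    def __init__(self, nin, nout, rng=None, gain=np.sqrt(2.0)):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, gain / np.sqrt(nin), size=(nin, nout)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, rng=None, train=False):
        return x @ self.w.value + self.b.value, x

    def backward(self, dy, cache):
        x = cache
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Flatten(Layer):
    def forward(self, x, rng=None, train=False):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dy, cache):
        return dy.reshape(cache)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, rng=None, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        patches = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = patches.argmax(axis=-1)
        y = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
        return y, (x.shape, idx)

    def backward(self, dy, cache):
        x_shape, idx = cache
        n, c, h, w = x_shape
        h2, w2 = h // 2, w // 2
        dpatch = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dpatch, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros(x_shape)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dpatch.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx


class UpsampleNearest2(Layer):
    def forward(self, x, rng=None, train=False):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, dy, cache):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class ReLU(Layer):
    def forward(self, x, rng=None, train=False):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x, rng=None, train=False):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, cache):
        return np.where(cache, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x, rng=None, train=False):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, cache):
        return dy * (1.0 - cache * cache)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p):
        self.p = p

    def forward(self, x, rng=None, train=False):
        if not train or self.p == 0.0:
            return x, None
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep, keep

    def backward(self, dy, cache):
        return dy if cache is None else dy * cache


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, c, eps=1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, rng=None, train=False):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        return y, (xhat, inv)

    def backward(self, dy, cache):
        xhat, inv = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = dy * self.gamma.value[None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        return (inv / m) * (m * g - g.sum(axis=(2, 3), keepdims=True)
                            - xhat * (g * xhat).sum(axis=(2, 3), keepdims=True))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, rng=None, train=False):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, rng=rng, train=train)
            caches.append(cache)
        return x, caches

    def backward(self, dy, caches):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, cache)
        return dy


class Residual(Layer):
    """y = x + body(x); the body must preserve shape."""

    def __init__(self, body: Sequential):
        self.body = body

    def params(self):
        return self.body.params()

    def forward(self, x, rng=None, train=False):
        y, cache = self.body.forward(x, rng=rng, train=train)
        return x + y, cache

    def backward(self, dy, cache):
        return dy + self.body.backward(dy, cache)


class Adam:
    """Adam with the standard bias correction (lr defaults match Kingma & Ba)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, onehot, sample_weights=None):
    """Mean weighted cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    w = np.ones(n) if sample_weights is None else np.asarray(sample_weights, float)
    ptrue = np.clip((p * onehot).sum(axis=1), 1e-7, None)
    loss = float(np.mean(w * -np.log(ptrue)))
    grad = (p - onehot) * (w / n)[:, None]
    return loss, grad
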