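"""Layers with explicit forward/backward passes (NHWC, float32).

Convolutions use TF-style "same" padding, so a stride-2 layer on even input
dims halves them exactly — the property the posture model's printed shape
table relies on.
"""

from __future__ import annotations

import numpy as np

from scipy.special import expit as sigmoid


def _same_pads(size: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def _pad_input(x: np.ndarray, k: int, stride: int):
    pt, pb = _same_pads(x.shape[1], k, stride)
    pl, pr = _same_pads(x.shape[2], k, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    return xp, (pt, pl)


def _tap(xp: np.ndarray, i: int, j: int, Ho: int, Wo: int, s: int) -> np.ndarray:
    """The (i, j) kernel-tap slice of a padded input, one value per output px."""
    return xp[:, i : i + Ho * s : s, j : j + Wo * s : s, :]


def conv2d_forward(x, W, stride):
    """x (N,H,W,Cin), W (k,k,Cin,Cout) -> (N,Ho,Wo,Cout); returns (out, cache).

    Computed as k*k accumulated GEMMs (one per kernel tap), which keeps all
    heavy lifting in BLAS without materializing im2col buffers.
    """
    k = W.shape[0]
    xp, off = _pad_input(x, k, stride)
    n = x.shape[0]
    Ho = -(-x.shape[1] // stride)
    Wo = -(-x.shape[2] // stride)
    out = np.zeros((n, Ho, Wo, W.shape[3]), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out += _tap(xp, i, j, Ho, Wo, stride) @ W[i, j]
    return out, (xp, off, x.shape, stride)


def conv2d_backward(dout, W, cache):
    """Returns (dx, dW) for conv2d_forward."""
    xp, (pt, pl), x_shape, stride = cache
    k = W.shape[0]
    _, Ho, Wo, _ = dout.shape
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            x_sl = _tap(xp, i, j, Ho, Wo, stride)
            dW[i, j] = np.tensordot(x_sl, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i : i + Ho * stride : stride, j : j + Wo * stride : stride, :] += (
                dout @ W[i, j].T
            )
    dx = dxp[:, pt : pt + x_shape[1], pl : pl + x_shape[2], :]
    return dx, dW


def depthwise_forward(x, W, stride):
    """x (N,H,W,C), W (k,k,C) -> (N,Ho,Wo,C); one spatial kernel per channel."""
    k = W.shape[0]
    xp, off = _pad_input(x, k, stride)
    Ho = -(-x.shape[1] // stride)
    Wo = -(-x.shape[2] // stride)
    out = np.zeros((x.shape[0], Ho, Wo, x.shape[3]), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out += _tap(xp, i, j, Ho, Wo, stride) * W[i, j]
    return out, (xp, off, x.shape, stride)


def depthwise_backward(dout, W, cache):
    xp, (pt, pl), x_shape, stride = cache
    k = W.shape[0]
    _, Ho, Wo, _ = dout.shape
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            x_sl = _tap(xp, i, j, Ho, Wo, stride)
            dW[i, j] = (dout * x_sl).sum(axis=(0, 1, 2))
            dxp[:, i : i + Ho * stride : stride, j : j + Wo * stride : stride, :] += (
                dout * W[i, j]
            )
    dx = dxp[:, pt : pt + x_shape[1], pl : pl + x_shape[2], :]
    return dx, dW


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def out_shape(self, shape: tuple) -> tuple:
        """Analytic output shape (no batch dim), for shape summaries."""
        raise NotImplementedError


class Conv2d(Layer):
    """Pointwise/standard convolution, 'same' padding, optional bias."""

    def __init__(self, cin, cout, k=1, stride=1, bias=True, rng=None, name="conv"):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * cin
        self.W = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, cin, cout)), f"{name}.W"
        )
        self.b = Param(np.zeros(cout), f"{name}.b") if bias else None
        self.stride = stride
        self._cache = None

    def forward(self, x, train=False):
        out, self._cache = conv2d_forward(x, self.W.data, self.stride)
        if self.b is not None:
            out += self.b.data
        return out

    def backward(self, grad):
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 1, 2))
        dx, dW = conv2d_backward(grad, self.W.data, self._cache)
        self.W.grad += dW
        return dx

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_shape(self, shape):
        h, w, _ = shape
        return (-(-h // self.stride), -(-w // self.stride), self.W.data.shape[3])


class DepthwiseConv2d(Layer):
    def __init__(self, c, k, stride=1, bias=True, rng=None, name="dwconv"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / (k * k)), (k, k, c)), f"{name}.W")
        self.b = Param(np.zeros(c), f"{name}.b") if bias else None
        self.stride = stride
        self._cache = None

    def forward(self, x, train=False):
        out, self._cache = depthwise_forward(x, self.W.data, self.stride)
        if self.b is not None:
            out += self.b.data
        return out

    def backward(self, grad):
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 1, 2))
        dx, dW = depthwise_backward(grad, self.W.data, self._cache)
        self.W.grad += dW
        return dx

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_shape(self, shape):
        h, w, c = shape
        return (-(-h // self.stride), -(-w // self.stride), c)


class BatchNorm2d(Layer):
    """Per-channel normalization over (N,H,W); running stats for eval mode."""

    def __init__(self, c, momentum=0.9, eps=1e-3, name="bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, x.shape, train)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad):
        xhat, inv_std, shape, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        if not train:
            # running stats are constants in eval mode
            return (grad * self.gamma.data * inv_std).astype(np.float32)
        m = shape[0] * shape[1] * shape[2]
        dxhat = grad * self.gamma.data
        dx = (
            inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 1, 2))
                - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
            )
        )
        return dx.astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def out_shape(self, shape):
        return shape


class GroupNorm2d(Layer):
    """Per-sample normalization over (H, W, channel-group).

    Batch-size independent: identical behaviour in train and eval mode, and
    no running statistics.  Preferred over batch statistics here because the
    backbone's late stages operate on 1x1-4x5 maps where a batch of eight
    provides no usable per-channel statistics.
    """

    def __init__(self, c, groups=8, eps=1e-5, name="gn"):
        self.groups = min(groups, c)
        while c % self.groups:
            self.groups -= 1
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        g = self.groups
        xg = x.reshape(n, h, w, g, c // g)
        mean = xg.mean(axis=(1, 2, 4), keepdims=True)
        var = xg.var(axis=(1, 2, 4), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mean) * inv_std).reshape(n, h, w, c)
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad):
        xhat, inv_std, (n, h, w, c) = self._cache
        g = self.groups
        m = h * w * (c // g)
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += grad.sum(axis=(0, 1, 2))
        dxh = (grad * self.gamma.data).reshape(n, h, w, g, c // g)
        xh = xhat.reshape(n, h, w, g, c // g)
        dx = (
            inv_std
            / m
            * (
                m * dxh
                - dxh.sum(axis=(1, 2, 4), keepdims=True)
                - xh * (dxh * xh).sum(axis=(1, 2, 4), keepdims=True)
            )
        )
        return dx.reshape(n, h, w, c).astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def out_shape(self, shape):
        return shape


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def out_shape(self, shape):
        return shape


class ReLU6(Layer):
    def forward(self, x, train=False):
        self._mask = (x > 0) & (x < 6.0)
        return np.clip(x, 0.0, 6.0)

    def backward(self, grad):
        return grad * self._mask

    def out_shape(self, shape):
        return shape


class SpatialDropout2d(Layer):
    """Drops whole feature maps; counters spatial correlation of activations."""

    def __init__(self, p, rng=None):
        assert 0.0 <= p < 1.0
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        mask = self.rng.random((x.shape[0], 1, 1, x.shape[3])) < keep
        self._mask = mask.astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def out_shape(self, shape):
        return shape


class Dropout(Layer):
    def __init__(self, p, rng=None):
        assert 0.0 <= p < 1.0
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def out_shape(self, shape):
        return shape


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).astype(
            np.float32
        )

    def out_shape(self, shape):
        return (shape[2],)


class Dense(Layer):
    def __init__(self, cin, cout, rng=None, name="dense"):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (cin + cout))
        self.W = Param(rng.uniform(-limit, limit, (cin, cout)), f"{name}.W")
        self.b = Param(np.zeros(cout), f"{name}.b")
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.data.T

    def params(self):
        return [self.W, self.b]

    def out_shape(self, shape):
        return (self.W.data.shape[1],)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def out_shape(self, shape):
        for layer in self.layers:
            shape = layer.out_shape(shape)
        return shape


class TimeDistributed(Layer):
    """Applies an inner layer to each timestep by folding time into batch."""

    def __init__(self, inner: Layer):
        self.inner = inner

    def forward(self, x, train=False):
        n, t = x.shape[:2]
        self._nt = (n, t)
        y = self.inner.forward(x.reshape((n * t,) + x.shape[2:]), train=train)
        return y.reshape((n, t) + y.shape[1:])

    def backward(self, grad):
        n, t = self._nt
        dx = self.inner.backward(grad.reshape((n * t,) + grad.shape[2:]))
        return dx.reshape((n, t) + dx.shape[1:])

    def params(self):
        return self.inner.params()

    def out_shape(self, shape):
        # shape = (t, h, w, c)
        return (shape[0],) + self.inner.out_shape(shape[1:])


class InvertedResidual(Layer):
    """MobileNetV2-style bottleneck: expand 1x1 -> depthwise 3x3 -> project 1x1,
    with a residual connection when the block preserves shape."""

    def __init__(self, cin, cout, stride, expand, rng=None, name="block"):
        mid = cin * expand
        layers: list[Layer] = []
        if expand != 1:
            layers += [
                Conv2d(cin, mid, 1, 1, bias=False, rng=rng, name=f"{name}.expand"),
                GroupNorm2d(mid, name=f"{name}.expand_gn"),
                ReLU6(),
            ]
        layers += [
            DepthwiseConv2d(mid, 3, stride, bias=False, rng=rng, name=f"{name}.dw"),
            GroupNorm2d(mid, name=f"{name}.dw_gn"),
            ReLU6(),
            Conv2d(mid, cout, 1, 1, bias=False, rng=rng, name=f"{name}.project"),
            GroupNorm2d(cout, name=f"{name}.project_gn"),
        ]
        self.body = Sequential(layers)
        self.residual = stride == 1 and cin == cout
        if self.residual:
            # zero-init the projection norm scale: the block starts as an
            # identity, which conditions deep stacks for fast early training
            layers[-1].gamma.data[...] = 0.0

    def forward(self, x, train=False):
        out = self.body.forward(x, train=train)
        return out + x if self.residual else out

    def backward(self, grad):
        dx = self.body.backward(grad)
        return dx + grad if self.residual else dx

    def params(self):
        return self.body.params()

    def out_shape(self, shape):
        return self.body.out_shape(shape)


class ConvLSTM(Layer):
    """Convolutional LSTM collapsing a (N,T,H,W,Cin) sequence to (N,H,W,F).

    Gates are 'same'-padded convolutions over the concatenation of the input
    frame and the previous hidden state; the final hidden state is returned,
    so the output is naturally biased toward the last frame of the sequence.
    Backward is full backpropagation through time.
    """

    def __init__(self, cin, filters, k=3, rng=None, name="convlstm"):
        rng = rng or np.random.default_rng(0)
        self.cin, self.F, self.k = cin, filters, k
        fan_in = k * k * (cin + filters)
        self.W = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, cin + filters, 4 * filters)),
            f"{name}.W",
        )
        bias = np.zeros(4 * filters, dtype=np.float32)
        bias[filters : 2 * filters] = 1.0  # forget-gate bias
        self.b = Param(bias, f"{name}.b")
        self._caches = None

    def forward(self, x, train=False):
        n, t, hh, ww, _ = x.shape
        F = self.F
        h = np.zeros((n, hh, ww, F), dtype=np.float32)
        c = np.zeros_like(h)
        caches = []
        for step in range(t):
            xa = np.concatenate([x[:, step], h], axis=-1)
            z, conv_cache = conv2d_forward(xa, self.W.data, 1)
            z += self.b.data
            i = sigmoid(z[..., :F])
            f = sigmoid(z[..., F : 2 * F])
            o = sigmoid(z[..., 2 * F : 3 * F])
            g = np.tanh(z[..., 3 * F :])
            c_prev = c
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            caches.append((conv_cache, i, f, o, g, c_prev, c))
        self._caches = (caches, x.shape)
        return h

    def backward(self, grad):
        caches, x_shape = self._caches
        n, t, hh, ww, cin = x_shape
        F = self.F
        dx = np.zeros(x_shape, dtype=np.float32)
        dh = grad
        dc = np.zeros_like(grad)
        for step in reversed(range(t)):
            conv_cache, i, f, o, g, c_prev, c = caches[step]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g**2),
                ],
                axis=-1,
            )
            self.b.grad += dz.sum(axis=(0, 1, 2))
            dxa, dW = conv2d_backward(dz, self.W.data, conv_cache)
            self.W.grad += dW
            dx[:, step] = dxa[..., :cin]
            dh = dxa[..., cin:]
            dc = dc * f
        return dx

    def params(self):
        return [self.W, self.b]

    def out_shape(self, shape):
        # (t, h, w, c) -> (h, w, F): the time axis is collapsed
        return (shape[1], shape[2], self.F)
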