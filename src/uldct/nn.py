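"""Minimal convolutional-network engine in NumPy.

Purpose-built layers (conv, instance norm, nearest-neighbour upsampling,
pointwise nonlinearities, residual blocks) with hand-written backward
passes and an Adam optimizer — everything the generator/discriminator
pair of the enhancement model needs, sized for CPU training of small
patch models.

The API is functional: ``forward`` returns ``(y, cache)`` and ``backward``
takes ``(dy, cache)`` and returns ``dx`` while accumulating parameter
gradients into ``Param.grad``.  Because caches live outside the layers, a
network can appear several times in one computation graph (the cycle
chains G_B(G_A(x)) reuse each generator twice per step).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Compute dtype. Single precision is the working precision of the
#: training loop (as in mainstream deep-learning frameworks); the
#: verified gradient accuracy is ~1e-3 relative, ample for Adam.
DTYPE = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution (cross-correlation) via im2col, zero padding."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, init_std, size=(out_ch, in_ch, k, k)), "w")
        self.b = Param(np.zeros(out_ch), "b")

    def params(self):
        return [self.w, self.b]

    def _im2col(self, x: np.ndarray):
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        return cols, (n, c, h, w, ho, wo)

    def forward(self, x: np.ndarray):
        cols, geom = self._im2col(x)
        n, c, h, w, ho, wo = geom
        wmat = self.w.data.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b.data
        y = y.transpose(0, 2, 1).reshape(n, self.out_ch, ho, wo)
        return y, (cols, geom)

    def backward(self, dy: np.ndarray, cache):
        cols, (n, c, h, w, ho, wo) = cache
        p, k, s = self.pad, self.k, self.stride
        dyf = dy.reshape(n, self.out_ch, ho * wo).transpose(0, 2, 1)
        wmat = self.w.data.reshape(self.out_ch, -1)
        ck = cols.shape[-1]
        self.w.grad += (
            dyf.reshape(-1, self.out_ch).T @ cols.reshape(-1, ck)
        ).reshape(self.w.data.shape)
        self.b.grad += dyf.sum(axis=(0, 1))
        dcols = dyf @ wmat  # (n, ho*wo, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization with affine parameters."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(ch), "gamma")
        self.beta = Param(np.zeros(ch), "beta")

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        return y, (xhat, inv)

    def backward(self, dy: np.ndarray, cache):
        xhat, inv = cache
        g = self.gamma.data[None, :, None, None]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        m = dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        ) * inv
        return dx


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, cache):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.slope * x), mask

    def backward(self, dy, cache):
        return np.where(cache, dy, self.slope * dy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, cache):
        return dy * (1.0 - cache**2)


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, dy, cache):
        return dy * cache * (1.0 - cache)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward sum-pools 2x2 blocks."""

    def forward(self, x):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, dy, cache):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy


class ResidualBlock(Layer):
    """conv-norm-relu-conv-norm with an identity skip."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.body = Sequential([
            Conv2d(ch, ch, 3, rng=rng), InstanceNorm(ch), ReLU(),
            Conv2d(ch, ch, 3, rng=rng), InstanceNorm(ch),
        ])

    def params(self):
        return self.body.params()

    def forward(self, x):
        y, c = self.body.forward(x)
        return x + y, c

    def backward(self, dy, cache):
        return dy + self.body.backward(dy, cache)


class Network:
    """A named parameterized network with gradient bookkeeping."""

    def __init__(self, net: Layer, name: str = ""):
        self.net = net
        self.name = name
        self._params = net.params()

    @property
    def params(self) -> list[Param]:
        return self._params

    def forward(self, x: np.ndarray):
        return self.net.forward(np.asarray(x, dtype=DTYPE))

    def backward(self, dy: np.ndarray, cache):
        return self.net.backward(np.asarray(dy, dtype=DTYPE), cache)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.forward(x)
        return y

    def zero_grad(self) -> None:
        for p in self._params:
            p.zero_grad()

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self._params]

    def load_state(self, state: list[np.ndarray]) -> None:
        if len(state) != len(self._params):
            raise ValueError("state length mismatch")
        for p, s in zip(self._params, state):
            p.data[...] = s


class Adam:
    """Adam with GAN-conventional betas (0.5, 0.999)."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * p.grad
            v[...] = self.b2 * v + (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def build_generator(
    rng: np.random.Generator,
    base_channels: int = 32,
    n_res_blocks: int = 4,
    width_multiplier: float = 1.0,
) -> Network:
    """Residual encoder-decoder generator (c7s1-F, two stride-2 downs,
    residual blocks, two upsampling stages, c7s1-1 with tanh head)."""
    f = max(4, int(round(base_channels * width_multiplier)))
    layers: list[Layer] = [
        Conv2d(1, f, 7, rng=rng), InstanceNorm(f), ReLU(),
        Conv2d(f, 2 * f, 3, stride=2, rng=rng), InstanceNorm(2 * f), ReLU(),
        Conv2d(2 * f, 4 * f, 3, stride=2, rng=rng), InstanceNorm(4 * f), ReLU(),
    ]
    layers += [ResidualBlock(4 * f, rng) for _ in range(n_res_blocks)]
    layers += [
        Upsample2x(), Conv2d(4 * f, 2 * f, 3, rng=rng), InstanceNorm(2 * f), ReLU(),
        Upsample2x(), Conv2d(2 * f, f, 3, rng=rng), InstanceNorm(f), ReLU(),
        Conv2d(f, 1, 7, rng=rng), Tanh(),
    ]
    return Network(Sequential(layers), "generator")


def build_discriminator(
    rng: np.random.Generator,
    base_channels: int = 32,
    width_multiplier: float = 1.0,
) -> Network:
    """3-layer patch discriminator with a sigmoid head (outputs in (0,1)).

    Deliberately norm-free: per-sample feature normalization would divide
    out the local noise amplitude, which is the very statistic that
    separates low-dose from normal-dose patches.
    """
    f = max(4, int(round(base_channels * width_multiplier)))
    layers: list[Layer] = [
        Conv2d(1, f, 4, stride=2, pad=1, rng=rng), LeakyReLU(),
        Conv2d(f, 2 * f, 4, stride=2, pad=1, rng=rng), LeakyReLU(),
        Conv2d(2 * f, 4 * f, 4, stride=1, pad=1, rng=rng), LeakyReLU(),
        Conv2d(4 * f, 1, 4, stride=1, pad=1, rng=rng), Sigmoid(),
    ]
    return Network(Sequential(layers), "discriminator")
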