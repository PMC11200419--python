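"""Minimal NumPy neural-network layers with manual backpropagation.

Supports the desk-scale conditional generators used by this package: 2D
convolutions (im2col), nearest-neighbour upsampling, leaky-ReLU / tanh /
sigmoid activations, dense layers for timestep embeddings, and Adam.  Layers
cache their forward inputs; ``backward`` consumes the loss gradient w.r.t.
the layer output and returns it w.r.t. the input, accumulating parameter
gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # training at desk scale is memory-bandwidth bound

__all__ = [
    "Param",
    "Conv2d",
    "Dense",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "UpsampleNearest",
    "Adam",
    "sinusoidal_embedding",
]


class Param:
    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _init_weight(shape, fan_in: int, init: str, rng: np.random.Generator) -> np.ndarray:
    if init == "zeros":
        return np.zeros(shape, dtype=DTYPE)
    if init in ("he", "standard", "kaiming"):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)
    raise ValueError(f"unknown init {init!r}")


class Conv2d:
    """Same-convention 2D convolution over NCHW arrays."""

    def __init__(self, cin, cout, k=3, stride=1, pad=1, init="he", rng=None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad, self.k = stride, pad, k
        self.W = Param(_init_weight((cout, cin, k, k), cin * k * k, init, rng))
        self.b = Param(np.zeros(cout, dtype=DTYPE))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
        cols2 = cols.reshape(n, c * k * k, oh * ow)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        out = np.matmul(wmat, cols2) + self.b.value[None, :, None]
        self._cache = (cols2, xp.shape, (oh, ow))
        return out.reshape(n, -1, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.ascontiguousarray(dout, dtype=DTYPE)
        cols2, xp_shape, (oh, ow) = self._cache
        n, cout = dout.shape[:2]
        k, s, p = self.k, self.stride, self.pad
        d2 = dout.reshape(n, cout, oh * ow)
        self.W.grad += np.matmul(d2, cols2.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.W.value.shape
        )
        self.b.grad += d2.sum(axis=(0, 2))
        wmat = self.W.value.reshape(cout, -1)
        dcols = np.matmul(wmat.T, d2)
        _, c, hp, wp = xp_shape
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        d6 = dcols.reshape(n, c, k, k, oh, ow)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += d6[:, :, i, j]
        return dxp[:, :, p : hp - p, p : wp - p] if p else dxp


class Dense:
    def __init__(self, din, dout, init="he", rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_init_weight((dout, din), din, init, rng))
        self.b = Param(np.zeros(dout, dtype=DTYPE))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


class LeakyReLU:
    def __init__(self, alpha=0.1):
        self.alpha = alpha
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class Tanh:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x):
        self._y = 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable sigmoid
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class UpsampleNearest:
    def __init__(self, factor=2):
        self.factor = factor

    def params(self):
        return []

    def forward(self, x):
        f = self.factor
        return x.repeat(f, axis=2).repeat(f, axis=3)

    def backward(self, dout):
        f = self.factor
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10_000.0) -> np.ndarray:
    """Standard transformer-style timestep embedding, shape (len(t), dim)."""
    t = np.asarray(t, dtype=np.float64).reshape(-1)
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if emb.shape[1] < dim:
        emb = np.pad(emb, ((0, 0), (0, dim - emb.shape[1])))
    return emb


class SmallUNet:
    """Two-level U-Net: encoder conv, strided downsample, bottleneck,
    nearest-upsample + conv, skip concatenation, output head.

    ``final`` selects the output activation ("tanh" for image synthesis,
    None for noise prediction).  ``time_dim`` > 0 adds a learned per-channel
    bias from a sinusoidal timestep embedding after the first encoder conv.
    """

    def __init__(self, in_ch, out_ch=1, base=16, final="tanh",
                 time_dim=0, init="he", rng=None):
        rng = rng or np.random.default_rng(0)
        self.enc1 = Conv2d(in_ch, base, 3, 1, 1, init, rng)
        self.act1 = LeakyReLU()
        self.down = Conv2d(base, 2 * base, 3, 2, 1, init, rng)
        self.act2 = LeakyReLU()
        self.mid = Conv2d(2 * base, 2 * base, 3, 1, 1, init, rng)
        self.act3 = LeakyReLU()
        self.upsample = UpsampleNearest(2)
        self.upconv = Conv2d(2 * base, base, 3, 1, 1, init, rng)
        self.act4 = LeakyReLU()
        self.dec = Conv2d(2 * base, base, 3, 1, 1, init, rng)
        self.act5 = LeakyReLU()
        self.head = Conv2d(base, out_ch, 3, 1, 1, init, rng)
        self.final = Tanh() if final == "tanh" else None
        self.time_dim = time_dim
        self.time_fc = Dense(time_dim, base, init, rng) if time_dim else None
        self.base = base
        self._cache = None

    def params(self):
        layers = [self.enc1, self.down, self.mid, self.upconv, self.dec, self.head]
        ps = [p for layer in layers for p in layer.params()]
        if self.time_fc is not None:
            ps += self.time_fc.params()
        return ps

    def forward(self, x: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
        h1 = self.act1.forward(self.enc1.forward(x))
        if self.time_fc is not None:
            emb = sinusoidal_embedding(t, self.time_dim)
            bias = self.time_fc.forward(emb)  # (N, base)
            h1 = h1 + bias[:, :, None, None].astype(h1.dtype)
        h2 = self.act2.forward(self.down.forward(h1))
        h3 = self.act3.forward(self.mid.forward(h2))
        h4 = self.act4.forward(self.upconv.forward(self.upsample.forward(h3)))
        cat = np.concatenate([h4, h1], axis=1)
        h5 = self.act5.forward(self.dec.forward(cat))
        out = self.head.forward(h5)
        if self.final is not None:
            out = self.final.forward(out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.final is not None:
            dout = self.final.backward(dout)
        d5 = self.dec.backward(self.act5.backward(self.head.backward(dout)))
        d4, dskip = d5[:, : self.base], d5[:, self.base :]
        d3 = self.upsample.backward(
            self.upconv.backward(self.act4.backward(d4))
        )
        d2 = self.mid.backward(self.act3.backward(d3))
        dh1 = self.down.backward(self.act2.backward(d2))
        dh1 = dh1 + dskip
        if self.time_fc is not None:
            self.time_fc.backward(dh1.sum(axis=(2, 3)))
        return self.enc1.backward(self.act1.backward(dh1))


class PatchDiscriminator:
    """Patch-based real/fake classifier with three convolutional layers.

    Strided convolutions shrink the receptive field map; the sigmoid head
    emits one probability per local patch rather than per image.
    """

    def __init__(self, in_ch, base=16, n_layers=3, init="he", rng=None):
        rng = rng or np.random.default_rng(0)
        self.layers = []
        c = in_ch
        width = base
        for i in range(n_layers - 1):
            self.layers.append(Conv2d(c, width, 4, 2, 1, init, rng))
            self.layers.append(LeakyReLU(0.2))
            c, width = width, width * 2
        self.layers.append(Conv2d(c, 1, 4, 1, 1, init, rng))
        self.layers.append(Sigmoid())

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
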