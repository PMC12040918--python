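"""Minimal numpy neural-network core for the U-Net.

Implements exactly the pieces the segmentation model needs — same-padded
convolutions via im2col, ReLU, 2x2 max pooling, nearest-neighbor 2x
upsampling, channel concatenation and Adam — with explicit forward and
backward passes.  Tensors are ``(N, C, H, W)`` float64.  Gradient
correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class Conv2D:
    """Same-padded k x k convolution (correlation) with optional ReLU."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator,
                 relu: bool = True):
        self.c_in, self.c_out, self.k, self.relu = c_in, c_out, ksize, relu
        fan_in = c_in * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, pad = self.k, self.k // 2
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            patches = np.empty((n, c, k * k, h, w))
            for u in range(k):
                for v in range(k):
                    patches[:, :, u * k + v] = xp[:, :, u : u + h, v : v + w]
            cols = patches.transpose(0, 3, 4, 1, 2).reshape(n, h * w, c * k * k)
        out = cols @ self.W + self.b
        if self.relu:
            mask = out > 0
            out = out * mask
        else:
            mask = None
        self._cache = (cols, mask, (n, c, h, w))
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, mask, (n, c, h, w) = self._cache
        k, pad = self.k, self.k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(n, h * w, self.c_out)
        if mask is not None:
            dflat = dflat * mask
        self.dW += cols.reshape(-1, cols.shape[-1]).T @ dflat.reshape(-1, self.c_out)
        self.db += dflat.sum(axis=(0, 1))
        dcols = dflat @ self.W.T
        if k == 1:
            return dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        dpatches = dcols.reshape(n, h, w, c, k * k).transpose(0, 3, 4, 1, 2)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        for u in range(k):
            for v in range(k):
                dxp[:, :, u : u + h, v : v + w] += dpatches[:, :, u * k + v]
        return dxp[:, :, pad : pad + h, pad : pad + w]


def maxpool2_forward(x):
    n, c, h, w = x.shape
    blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2_backward(dout, idx, shape):
    n, c, h, w = shape
    dflat = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    return (
        dflat.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def upsample2_forward(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Symmetric encoder-decoder with skip connections and sigmoid output.

    ``depth`` down/up-sampling levels, ``base_filters`` feature maps at the
    first level doubling per level, two 3x3 conv+ReLU per block, 2x2 max
    pooling, nearest-neighbor upsampling followed by a channel-halving 3x3
    convolution, skip concatenation, and a final 1x1 projection whose
    elementwise sigmoid gives per-class probabilities in (0, 1).
    Spatial input size must be divisible by ``2**depth``.
    """

    def __init__(self, depth: int, base_filters: int, in_channels: int,
                 out_channels: int, seed: int = 0):
        if depth < 1 or base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        self.depth, self.base_filters = depth, base_filters
        self.in_channels, self.out_channels = in_channels, out_channels
        rng = np.random.default_rng(seed)
        f = base_filters
        self.enc = []
        c_prev = in_channels
        for i in range(depth):
            c = f * 2**i
            self.enc.append(
                (Conv2D(c_prev, c, 3, rng), Conv2D(c, c, 3, rng))
            )
            c_prev = c
        cb = f * 2**depth
        self.bottleneck = (Conv2D(c_prev, cb, 3, rng), Conv2D(cb, cb, 3, rng))
        self.up = []
        self.dec = []
        c_prev = cb
        for i in reversed(range(depth)):
            c = f * 2**i
            self.up.append(Conv2D(c_prev, c, 3, rng))
            self.dec.append((Conv2D(2 * c, c, 3, rng), Conv2D(c, c, 3, rng)))
            c_prev = c
        self.head = Conv2D(c_prev, out_channels, 1, rng, relu=False)

    def _layers(self):
        for a, b in self.enc:
            yield a
            yield b
        yield self.bottleneck[0]
        yield self.bottleneck[1]
        for u, (a, b) in zip(self.up, self.dec):
            yield u
            yield a
            yield b
        yield self.head

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for layer in self._layers():
            layer.dW[:] = 0.0
            layer.db[:] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map ``(N, in, H, W)`` to per-class probabilities ``(N, out, H, W)``."""
        n, c, h, w = x.shape
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2**depth = {2**self.depth}"
            )
        self._pool_caches = []
        skips = []
        for conv1, conv2 in self.enc:
            x = conv2.forward(conv1.forward(x))
            skips.append(x)
            pooled, idx = maxpool2_forward(x)
            self._pool_caches.append((idx, x.shape))
            x = pooled
        x = self.bottleneck[1].forward(self.bottleneck[0].forward(x))
        self._skip_channels = []
        for up, (conv1, conv2), skip in zip(self.up, self.dec, reversed(skips)):
            x = up.forward(upsample2_forward(x))
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = conv2.forward(conv1.forward(x))
        logits = self.head.forward(x)
        self._probs = expit(logits)  # numerically stable sigmoid
        return self._probs

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dx = self.head.backward(dlogits)
        dskips = []
        for up, (conv1, conv2), c_skip in zip(
            reversed(self.up), reversed(self.dec), reversed(self._skip_channels)
        ):
            dcat = conv1.backward(conv2.backward(dx))
            dskips.append(dcat[:, :c_skip])
            dx = upsample2_backward(up.backward(dcat[:, c_skip:]))
        dx = self.bottleneck[0].backward(self.bottleneck[1].backward(dx))
        # dskips were collected shallowest-first; encoder unwinds deepest-first
        for (conv1, conv2), (idx, shape), dskip in zip(
            reversed(self.enc), reversed(self._pool_caches), reversed(dskips)
        ):
            dx = maxpool2_backward(dx, idx, shape) + dskip
            dx = conv1.backward(conv2.backward(dx))
        # dx w.r.t. the input is discarded

    def state(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def load_state(self, arrays) -> None:
        arrays = list(arrays)
        i = 0
        for layer in self._layers():
            layer.W[:] = arrays[i]
            layer.b[:] = arrays[i + 1]
            i += 2


class Adam:
    """Adam optimizer over (param, grad) pairs; learning rate set per step."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
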