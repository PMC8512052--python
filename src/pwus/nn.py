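"""Minimal NumPy neural-network stack for the U-Net segmenter.

Implements exactly the pieces a small encoder/decoder segmentation
network needs: 2-D convolutions (im2col + matmul), ReLU, 2x2 max pooling,
factor-2 bilinear up-sampling with its exact adjoint, channel
concatenation, pixelwise softmax cross-entropy and Adam. Layers are
stateful (they cache forward activations for the following backward
pass), which is sufficient for plain sequential training and keeps the
code small and dependency-free.

All gradients are exact (verified against finite differences in the test
suite), not approximations.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Upsample2", "ConvBlock", "UNet",
           "softmax_cross_entropy", "Adam"]


class Conv2d:
    """3x3 (or 1x1) same-padding convolution, stride 1, with bias.

    He-normal initialization. Input/output layout is (N, C, H, W).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, (c_out, c_in, k, k)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.k = k
        self._cols = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        self._cols = cols
        y = np.einsum("nchwij,ocij->nohw", cols, self.W, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        self.gW += np.einsum("nchwij,nohw->ocij", self._cols, dy, optimize=True)
        self.gb += dy.sum(axis=(0, 2, 3))
        wf = self.W[:, :, ::-1, ::-1]
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(dyp, (k, k), axis=(2, 3))
        dx = np.einsum("nohwij,ocij->nchw", cols, wf, optimize=True)
        self._cols = None
        return dx

    def params(self):
        return [(self, "W", "gW"), (self, "b", "gb")]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling with stride 2; input sides must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("pooling input sides must be even")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        g = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(g, self._arg[..., None], dy[..., None], axis=-1)
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)

    def params(self):
        return []


@lru_cache(maxsize=None)
def _up2_matrix(n: int) -> np.ndarray:
    """Dense (2n, n) factor-2 bilinear interpolation matrix (edge-clamped)."""
    m = np.zeros((2 * n, n))
    for i in range(2 * n):
        c = i / 2.0 - 0.25
        i0 = int(np.floor(c))
        w1 = c - i0
        m[i, min(max(i0, 0), n - 1)] += 1.0 - w1
        m[i, min(max(i0 + 1, 0), n - 1)] += w1
    return m


class Upsample2:
    """Factor-2 bilinear up-sampling; backward is the exact adjoint."""

    def forward(self, x):
        n, c, h, w = x.shape
        self._hw = (h, w)
        mh = _up2_matrix(h).astype(x.dtype)
        mw = _up2_matrix(w).astype(x.dtype)
        return np.matmul(np.matmul(mh, x), mw.T)

    def backward(self, dy):
        h, w = self._hw
        mh = _up2_matrix(h).astype(dy.dtype)
        mw = _up2_matrix(w).astype(dy.dtype)
        return np.matmul(np.matmul(mh.T, dy), mw)

    def params(self):
        return []


class ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, c_in, c_out, rng, dtype=np.float32):
        self.layers = [Conv2d(c_in, c_out, 3, rng, dtype), ReLU(),
                       Conv2d(c_out, c_out, 3, rng, dtype), ReLU()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]


class UNet:
    """Symmetric encoder/decoder segmentation network.

    ``depth`` blocks per path with channel counts
    ``first_channels * growth**k``; 2x2 max pooling between encoder
    levels; decoder levels bilinearly up-sample, convolve down to the
    skip width, concatenate the skip connection and convolve again; a
    final 1x1 convolution maps to the class scores.
    Input sides must be divisible by ``2**(depth-1)``.
    """

    def __init__(self, in_channels=1, n_classes=2, depth=5, first_channels=6,
                 growth=2, seed=0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.dtype = dtype
        ch = [first_channels * growth**k for k in range(depth)]
        self.channels = ch
        self.enc = []
        c_prev = in_channels
        for k in range(depth):
            self.enc.append(ConvBlock(c_prev, ch[k], rng, dtype))
            c_prev = ch[k]
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = [Upsample2() for _ in range(depth - 1)]
        self.up_convs = [Conv2d(ch[k + 1], ch[k], 3, rng, dtype) for k in range(depth - 1)]
        self.up_relus = [ReLU() for _ in range(depth - 1)]
        self.dec = [ConvBlock(2 * ch[k], ch[k], rng, dtype) for k in range(depth - 1)]
        self.head = Conv2d(ch[0], n_classes, 1, rng, dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        h, w = x.shape[2:]
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(f"input sides must be divisible by {div}")
        skips = []
        for k in range(self.depth):
            x = self.enc[k].forward(x)
            if k < self.depth - 1:
                skips.append(x)
                x = self.pools[k].forward(x)
        self._skip_channels = [s.shape[1] for s in skips]
        for k in range(self.depth - 2, -1, -1):
            x = self.ups[k].forward(x)
            x = self.up_relus[k].forward(self.up_convs[k].forward(x))
            x = np.concatenate([skips[k], x], axis=1)
            x = self.dec[k].forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = [None] * (self.depth - 1)
        for k in range(self.depth - 1):
            dy = self.dec[k].backward(dy)
            cs = self._skip_channels[k]
            dskips[k] = dy[:, :cs]
            dy = self.up_relus[k].backward(dy[:, cs:])
            dy = self.up_convs[k].backward(dy)
            dy = self.ups[k].backward(dy)
        for k in range(self.depth - 1, -1, -1):
            if k < self.depth - 1:
                dy = self.pools[k].backward(dy)
                dy = dy + dskips[k]
            dy = self.enc[k].backward(dy)

    def params(self):
        out = []
        for blk in self.enc + self.up_convs + self.dec + [self.head]:
            out.extend(blk.params())
        return out

    def zero_grad(self):
        for obj, _, gname in self.params():
            getattr(obj, gname)[...] = 0.0

    # --- flat (de)serialization -------------------------------------------
    def state_arrays(self):
        return [getattr(obj, name) for obj, name, _ in self.params()]

    def load_state_arrays(self, arrays):
        own = self.params()
        if len(arrays) != len(own):
            raise ValueError("parameter count mismatch")
        for (obj, name, _), arr in zip(own, arrays):
            cur = getattr(obj, name)
            if cur.shape != arr.shape:
                raise ValueError("parameter shape mismatch")
            setattr(obj, name, np.asarray(arr, dtype=cur.dtype))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean pixelwise cross-entropy and its gradient w.r.t. the logits.

    ``logits`` is (N, K, H, W); ``labels`` is (N, H, W) of class indices.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n, k, h, w = logits.shape
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
    count = n * h * w
    loss = -np.sum(onehot * np.log(np.maximum(p, 1e-12))) / count
    return float(loss), ((p - onehot) / count).astype(logits.dtype)


class Adam:
    """Adam optimizer over a network's (param, grad) attribute pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n)) for o, n, _ in params]
        self.v = [np.zeros_like(getattr(o, n)) for o, n, _ in params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (obj, name, gname) in enumerate(self.params):
            g = getattr(obj, gname)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            upd = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            p = getattr(obj, name)
            setattr(obj, name, p - (self.lr * upd).astype(p.dtype))
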