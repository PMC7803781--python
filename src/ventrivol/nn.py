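"""Minimal numpy neural-network primitives for per-slice segmentation.

Implements exactly what the slice segmenter needs -- same-padded 3x3
convolution via im2col, ReLU, 2x2 max pooling, nearest-neighbour
2x upsampling, a class-weighted softmax cross-entropy, and SGD with
momentum and L2 weight decay -- with hand-written backward passes.
Everything is float32 and deterministic given the initialisation RNG.

Tensor layout is (N, C, H, W) throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer; stateless layers only implement forward/backward."""

    params: list  # list of [array, grad, momentum] triples

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(n, c, h, w) -> (n*h*w, c*k*k) patches of the same-padded input."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Conv2d(Layer):
    """Same-padded stride-1 convolution (cross-correlation) via im2col.

    The input gradient is itself a same-padded correlation of the output
    gradient with the spatially flipped, channel-transposed kernel, so
    backward reuses the im2col path instead of a scatter loop.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.w = w.astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.params = [[self.w, self.gw, np.zeros_like(self.w)],
                       [self.b, self.gb, np.zeros_like(self.b)]]
        self._cols = None
        self._xshape = None

    def forward(self, x, train):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.w.reshape(self.c_out, -1).T + self.b
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, _, h, w = self._xshape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        dflat = np.ascontiguousarray(dflat, dtype=np.float32)
        self.gw[...] = (dflat.T @ self._cols).reshape(self.w.shape)
        self.gb[...] = dflat.sum(axis=0)
        self._cols = None
        # dx = same-padded correlation of dout with flipped/transposed kernel
        w_t = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        dcols = _im2col(dout.astype(np.float32, copy=False), self.k)
        dx = dcols @ w_t.reshape(self.c_in, -1).T
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; gradient routed to the first argmax."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x, train):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def weighted_softmax_ce(
    logits: np.ndarray, target: np.ndarray, alpha: np.ndarray
) -> tuple[float, np.ndarray]:
    """Pixelwise class-weighted cross-entropy.

    ``alpha`` maps class index to weight; the loss is the weighted mean
    of per-pixel negative log-likelihoods, sum(w * nll) / sum(w), which
    reduces to plain mean cross-entropy when all weights are 1.
    Returns (loss, dloss/dlogits).
    """
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    t = target.astype(np.int64)
    wpix = alpha[t].astype(np.float32)  # (n, h, w)
    idx = np.ogrid[:n, :h, :w]
    nll = -np.log(np.maximum(p[idx[0], t, idx[1], idx[2]], 1e-12))
    wsum = float(wpix.sum())
    loss = float((wpix * nll).sum() / wsum)
    onehot = np.zeros_like(p)
    onehot[idx[0], t, idx[1], idx[2]] = 1.0
    dlogits = (p - onehot) * wpix[:, None, :, :] / wsum
    return loss, dlogits.astype(np.float32)


class SGD:
    """SGD with classical momentum and decoupled-from-nothing L2 decay."""

    def __init__(self, layers, lr: float, momentum: float, weight_decay: float):
        self.layers = layers
        self.lr, self.mu, self.wd = lr, momentum, weight_decay

    def step(self):
        for layer in self.layers:
            for p, g, v in layer.params:
                np.multiply(v, self.mu, out=v)
                v -= self.lr * (g + self.wd * p)
                p += v


class Sequential:
    """A plain layer chain with forward/backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def state_arrays(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p, _, _ in layer.params]
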