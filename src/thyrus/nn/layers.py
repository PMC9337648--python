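"""Minimal float32 CNN layer zoo with manual backpropagation.

Only what the encoder–decoder segmentation network needs: 2D convolution
(im2col + BLAS matmul), batch normalization, ReLU, 2×2 max-pooling that
exports its argmax indices, the matching index unpooling, channel dropout,
and Adam.  All tensors are channels-last, (N, H, W, C): that layout keeps
the channel axis contiguous, so im2col reduces to k² contiguous block copies
and 1×1 convolutions to a single matmul.  Layers cache what their backward
pass needs; ``backward`` must be called in reverse order of ``forward``
within one optimization step.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _pad_flat(x: np.ndarray, k: int) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Zero-pad (N,H,W,C) for a same conv and flatten to (rows, C).

    The returned buffer has `k-1` extra zero rows at the tail so that every
    shifted view ``flat[off : off + N·Hp·Wp]`` with ``off = di·Wp + dj`` is in
    bounds.  Shifted views turn the k×k convolution into k² GEMMs on
    contiguous memory with no im2col gather.
    """
    n, h, w, c = x.shape
    p = k // 2
    hp, wp = h + 2 * p, w + 2 * p
    tail = (k - 1) * wp + (k - 1)
    flat = np.zeros((n * hp * wp + tail, c), dtype=F32)
    flat[: n * hp * wp].reshape(n, hp, wp, c)[:, p : p + h, p : p + w] = x
    return flat, (n, hp, wp, c)


def _shift_conv(flat: np.ndarray, geom: tuple[int, int, int, int], W: np.ndarray,
                out_hw: tuple[int, int]) -> np.ndarray:
    """Σ_{di,dj} flat[off:off+L] @ W[di,dj]; crop the padded grid to out_hw."""
    n, hp, wp, _ = geom
    k = W.shape[0]
    o = W.shape[3]
    L = n * hp * wp
    acc = np.zeros((L, o), dtype=F32)
    tmp = np.empty((L, o), dtype=F32)
    for di in range(k):
        for dj in range(k):
            np.dot(flat[di * wp + dj : di * wp + dj + L], W[di, dj], out=tmp)
            acc += tmp
    h, w = out_hw
    return np.ascontiguousarray(acc.reshape(n, hp, wp, o)[:, :h, :w])


class Layer:
    def parameters(self):  # [(param_array, grad_array), ...] — mutated in place
        return []


class Conv2d(Layer):
    """Same-padded stride-1 convolution; He-normal init.

    Weights are stored as (k, k, C_in, C_out) to match the im2col patch order.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, in_ch, out_ch)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        self._shape = (n, h, w)
        if self.k == 1:
            xf = np.ascontiguousarray(x).reshape(-1, c)
            self._cache = ("1x1", xf)
            y = (xf @ self.W.reshape(c, self.out_ch)).reshape(n, h, w, self.out_ch)
            return y + self.b
        flat, geom = _pad_flat(x, self.k)
        self._cache = ("kxk", flat, geom)
        return _shift_conv(flat, geom, self.W, (h, w)) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w = self._shape
        dy = np.ascontiguousarray(dy, dtype=F32)
        dyf = dy.reshape(-1, self.out_ch)
        self.db += dyf.sum(axis=0)
        if self._cache[0] == "1x1":
            xf = self._cache[1]
            self.dW += (xf.T @ dyf).reshape(self.dW.shape)
            dx = dyf @ self.W.reshape(self.in_ch, self.out_ch).T
            return dx.reshape(n, h, w, self.in_ch)
        _, flat, geom = self._cache
        _, hp, wp, _ = geom
        L = n * hp * wp
        # dy scattered onto the uncropped output grid (zeros where cropped away)
        dy2 = np.zeros((L, self.out_ch), dtype=F32)
        dy2.reshape(n, hp, wp, self.out_ch)[:, :h, :w] = dy
        k = self.k
        for di in range(k):
            for dj in range(k):
                off = di * wp + dj
                self.dW[di, dj] += flat[off : off + L].T @ dy2
        # grad wrt input = same-padded correlation of dy with the flipped kernel
        w_flip = np.ascontiguousarray(self.W[::-1, ::-1].transpose(0, 1, 3, 2))
        flat_dy, geom_dy = _pad_flat(dy, k)
        return _shift_conv(flat_dy, geom_dy, w_flip, (h, w))


class BatchNorm2d(Layer):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch, dtype=F32)
        self.beta = np.zeros(n_ch, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_ch, dtype=F32)
        self.running_var = np.ones(n_ch, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean += self.momentum * (mean.astype(F32) - self.running_mean)
            self.running_var += self.momentum * (var.astype(F32) - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean) * ivar
        if training:
            self._cache = (xhat, ivar)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.dgamma += (dy * xhat).sum(axis=(0, 1, 2))
        self.dbeta += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (ivar / m) * (m * dxhat - s1 - xhat * s2)
        return dx.astype(F32, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0.0))


def _to_quads(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C) -> contiguous (N,H/2,W/2,4,C) of 2×2 neighbourhoods."""
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)


def _from_quads(q: np.ndarray) -> np.ndarray:
    n, h2, w2, _, c = q.shape
    x = q.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return np.ascontiguousarray(x).reshape(n, 2 * h2, 2 * w2, c)


class MaxPool2d(Layer):
    """2×2, stride 2; keeps argmax indices for the matching unpooling."""

    def forward(self, x: np.ndarray, training: bool = False):
        if x.shape[1] % 2 or x.shape[2] % 2:
            raise ValueError("pooling requires even spatial dimensions")
        quads = _to_quads(x)
        idx = quads.argmax(axis=3)
        y = np.take_along_axis(quads, idx[:, :, :, None], axis=3)[:, :, :, 0]
        self._idx = idx
        return y, idx

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return unpool_scatter(dy, self._idx)


def unpool_scatter(y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Place y values at the recorded 2×2 argmax positions, zeros elsewhere."""
    n, h2, w2, c = y.shape
    z = np.zeros((n, h2, w2, 4, c), dtype=y.dtype)
    np.put_along_axis(z, idx[:, :, :, None], y[:, :, :, None], axis=3)
    return _from_quads(z)


class MaxUnpool2d(Layer):
    """Index unpooling: inverse scatter of the encoder's 2×2 max-pooling."""

    def forward(self, x: np.ndarray, idx: np.ndarray, training: bool = False) -> np.ndarray:
        self._idx = idx
        return unpool_scatter(x, idx)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        quads = _to_quads(dy)
        return np.take_along_axis(quads, self._idx[:, :, :, None], axis=3)[:, :, :, 0]


class Dropout2d(Layer):
    """Channel (spatial) dropout; identity at eval time."""

    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p <= 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout rng not set; call model.set_dropout_rng first")
        keep = (self.rng.random((x.shape[0], 1, 1, x.shape[3])) >= self.p).astype(F32)
        self._mask = keep / F32(1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
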