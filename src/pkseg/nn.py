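"""Minimal NumPy neural-network layers with explicit backpropagation.

The segmentation network runs on CPU with batch size one; every layer
operates on a single ``(channels, depth, height, width)`` float32 tensor.
Convolutions are evaluated as one BLAS matrix product per kernel offset
("shift-and-matmul"), which keeps peak memory near the activation size
even for full-size patches.

Layers cache their inputs only when ``train=True``; inference never holds
intermediate activations beyond the current stage.
"""

from __future__ import annotations

import numpy as np

def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3, got {v!r}")
    return t


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
           stride: tuple[int, int, int]) -> np.ndarray:
    """'Same'-padded strided 3D convolution (cross-correlation).

    x: (Ci, D, H, W); w: (Co, Ci, kd, kh, kw); output (Co, D', H', W') with
    D' = ceil(D / stride_d) etc. (padding k//2 on both sides).
    """
    ci, d, h, wd = x.shape
    co, ci2, kd, kh, kw = w.shape
    assert ci == ci2, (ci, ci2)
    sd, sh, sw = stride
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
    do = (d + 2 * pd - kd) // sd + 1
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    # shift-and-matmul: one BLAS product per kernel offset, summed; this
    # avoids the k^3-fold im2col copy and its cache-hostile gather
    acc = np.zeros((co, do * ho * wo), dtype=np.float32)
    for a in range(kd):
        for bb in range(kh):
            for c in range(kw):
                xs = xp[:, a:a + sd * do:sd, bb:bb + sh * ho:sh,
                        c:c + sw * wo:sw].reshape(ci, -1)
                acc += w[:, :, a, bb, c] @ xs
    out = acc.reshape(co, do, ho, wo)
    if b is not None:
        out += b[:, None, None, None]
    return out


def conv3d_grad_input(gy: np.ndarray, w: np.ndarray, x_shape,
                      stride: tuple[int, int, int]) -> np.ndarray:
    """Gradient of conv3d w.r.t. its input (a transposed convolution)."""
    ci, d, h, wd = x_shape
    co, _, kd, kh, kw = w.shape
    sd, sh, sw = stride
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    do, ho, wo = gy.shape[1:]
    gxp = np.zeros((ci, d + 2 * pd, h + 2 * ph, wd + 2 * pw), dtype=np.float32)
    for a in range(kd):
        for bb in range(kh):
            for c in range(kw):
                # (Co,Ci) x (Co,Do,Ho,Wo) -> (Ci,Do,Ho,Wo)
                g = np.tensordot(w[:, :, a, bb, c], gy, axes=([0], [0]))
                gxp[:, a:a + sd * do:sd, bb:bb + sh * ho:sh,
                    c:c + sw * wo:sw] += g
    return gxp[:, pd:pd + d, ph:ph + h, pw:pw + wd]


def conv3d_grad_weight(x: np.ndarray, gy: np.ndarray, w_shape,
                       stride: tuple[int, int, int]) -> np.ndarray:
    co, ci, kd, kh, kw = w_shape
    sd, sh, sw = stride
    pd, ph, pw = kd // 2, kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw)))
    do, ho, wo = gy.shape[1:]
    gmat = gy.reshape(co, -1)
    gw = np.empty(w_shape, dtype=np.float32)
    for a in range(kd):
        for bb in range(kh):
            for c in range(kw):
                xs = xp[:, a:a + sd * do:sd, bb:bb + sh * ho:sh,
                        c:c + sw * wo:sw].reshape(ci, -1)
                gw[:, :, a, bb, c] = gmat @ xs.T
    return gw


class Conv3d:
    """Strided 3D convolution with 'same' padding and He-normal init."""

    def __init__(self, c_in: int, c_out: int, kernel, stride=1,
                 rng: np.random.Generator | None = None):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        rng = rng or np.random.default_rng()
        fan_in = c_in * int(np.prod(self.kernel))
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, *self.kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return conv3d(x, self.w, self.b, self.stride)

    def backward(self, gy):
        x = self._x
        self.gw += conv3d_grad_weight(x, gy, self.w.shape, self.stride)
        self.gb += gy.sum(axis=(1, 2, 3))
        return conv3d_grad_input(gy, self.w, x.shape, self.stride)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ConvTranspose3d:
    """Transposed convolution with kernel == stride (pure upsampling).

    With the kernel tiling exactly (no overlap) the operator interleaves a
    learned kernel at every input voxel, doubling/quadrupling the grid.
    """

    def __init__(self, c_in: int, c_out: int, stride,
                 rng: np.random.Generator | None = None):
        self.stride = _triple(stride)
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in),
                            size=(c_in, c_out, *self.stride)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        ci, d, h, wd = x.shape
        kd, kh, kw = self.stride
        co = self.w.shape[1]
        y = np.tensordot(self.w, x, axes=([0], [0]))  # (Co,kd,kh,kw,D,H,W)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3).reshape(co, d * kd, h * kh, wd * kw)
        y += self.b[:, None, None, None]
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gy):
        x = self._x
        kd, kh, kw = self.stride
        co, dd, hh, ww = gy.shape
        d, h, wd = dd // kd, hh // kh, ww // kw
        g = gy.reshape(co, d, kd, h, kh, wd, kw).transpose(0, 2, 4, 6, 1, 3, 5)
        # (Co,kd,kh,kw,D,H,W)
        self.gw += np.tensordot(x, g, axes=([1, 2, 3], [4, 5, 6]))
        self.gb += gy.sum(axis=(1, 2, 3))
        gx = np.tensordot(self.w, g, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
        return np.ascontiguousarray(gx, dtype=np.float32)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class InstanceNorm3d:
    """Per-channel normalization over the spatial axes with affine scale."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x, train=False):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv.astype(np.float32))
        return (self.gamma[:, None, None, None] * xhat
                + self.beta[:, None, None, None]).astype(np.float32)

    def backward(self, gy):
        xhat, inv = self._cache
        n = xhat[0].size
        self.ggamma += (gy * xhat).sum(axis=(1, 2, 3))
        self.gbeta += gy.sum(axis=(1, 2, 3))
        gxhat = gy * self.gamma[:, None, None, None]
        mean_g = gxhat.mean(axis=(1, 2, 3), keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return ((gxhat - mean_g - xhat * mean_gx) * inv).astype(np.float32)

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x).astype(np.float32)

    def backward(self, gy):
        return np.where(self._mask, gy, self.slope * gy).astype(np.float32)

    def params(self):
        return []


class ConvBlock:
    """conv -> instance norm -> leaky ReLU, the repeating unit of the net."""

    def __init__(self, c_in, c_out, kernel, stride=1, rng=None):
        self.conv = Conv3d(c_in, c_out, kernel, stride, rng)
        self.norm = InstanceNorm3d(c_out)
        self.act = LeakyReLU()

    def forward(self, x, train=False):
        return self.act.forward(
            self.norm.forward(self.conv.forward(x, train), train), train)

    def backward(self, gy):
        return self.conv.backward(self.norm.backward(self.act.backward(gy)))

    def params(self):
        return self.conv.params() + self.norm.params()


class SGD:
    """SGD with Nesterov-style momentum and optional weight decay."""

    def __init__(self, params, lr=0.01, momentum=0.9, weight_decay=0.0):
        self.params = params  # list of (value, grad) array pairs
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.vel = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for (p, g), v in zip(self.params, self.vel):
            if self.weight_decay:
                g = g + self.weight_decay * p
            v *= self.momentum
            v -= self.lr * g
            p += self.momentum * v - self.lr * g

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0
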