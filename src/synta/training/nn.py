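"""Minimal numpy building blocks for the segmentation network.

Self-contained layers with explicit forward/backward passes (no autodiff
framework): 3x3 same-padding convolution via im2col, group normalization,
ReLU, 2x2 max pooling, bilinear 2x upsampling (with its exact adjoint for
the backward pass) and an Adam optimizer.  Tensors are (N, C, H, W) float32;
sizes in this package are small enough that matmul-based convolution on one
CPU is entirely adequate.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Conv1x1",
    "GroupNorm",
    "ReLU",
    "MaxPool2",
    "BilinearUp2",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches of the zero-padded input."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (N, C, H, W, 3, 3) -> (N, C, 3, 3, H, W) -> (N, C*9, H*W)
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * 9, h * w)


class Conv2d:
    """3x3 convolution, stride 1, same padding, He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [("w", self.w), ("b", self.b)]
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        self._cols, self._xshape = cols, x.shape
        wf = self.w.reshape(self.w.shape[0], -1)
        y = np.einsum("of,nfp->nop", wf, cols, optimize=True)
        return y.reshape(n, -1, h, w) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, co, h, w = dy.shape
        dyf = dy.reshape(n, co, h * w)
        self.db = dyf.sum(axis=(0, 2)).astype(np.float32)
        self.dw = (
            np.einsum("nop,nfp->of", dyf, self._cols, optimize=True)
            .reshape(self.w.shape)
            .astype(np.float32)
        )
        # backward-data of a same-padded 3x3 conv = conv with the spatially
        # flipped, channel-transposed kernel
        w_flip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols_dy = _im2col3(dy)
        dx = np.einsum(
            "of,nfp->nop", w_flip.reshape(w_flip.shape[0], -1), cols_dy, optimize=True
        )
        self._cols = None
        return dx.reshape(self._xshape).astype(np.float32)

    def grads(self):
        return [self.dw, self.db]


class Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_out, c_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,nchw->nohw", self.w, x, optimize=True) + self.b[
            None, :, None, None
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = np.einsum("nohw,nchw->oc", dy, self._x, optimize=True).astype(np.float32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        self._x = None
        return np.einsum("oc,nohw->nchw", self.w, dy, optimize=True).astype(np.float32)

    def grads(self):
        return [self.dw, self.db]


class GroupNorm:
    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        self.g = min(groups, channels)
        while channels % self.g:
            self.g -= 1
        self.eps = eps
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.params = [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xg = x.reshape(n, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        self._xhat = ((xg - mu) / np.sqrt(var + self.eps)).astype(np.float32)
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._shape = x.shape
        xh = self._xhat.reshape(n, c, h, w)
        return xh * self.gamma[None, :, None, None] + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        xh = self._xhat.reshape(n, c, h, w)
        self.dgamma = (dy * xh).sum(axis=(0, 2, 3)).astype(np.float32)
        self.dbeta = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        dxh = (dy * self.gamma[None, :, None, None]).reshape(n, self.g, -1)
        xhg = self._xhat
        m = dxh.shape[2]
        dx = (
            self._istd
            / m
            * (m * dxh - dxh.sum(axis=2, keepdims=True) - xhg * (dxh * xhg).sum(axis=2, keepdims=True))
        )
        self._xhat = None
        return dx.reshape(n, c, h, w).astype(np.float32)

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def grads(self):
        return []


class MaxPool2:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._idx = xr.argmax(axis=4)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=4)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=4)
        dx = (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._idx = None
        return dx

    def grads(self):
        return []


class BilinearUp2:
    """Bilinear 2x upsampling; backward is the exact adjoint (scatter-add)."""

    params: list = []

    def _plan(self, size: int):
        src = (np.arange(2 * size) + 0.5) / 2.0 - 0.5
        i0 = np.clip(np.floor(src).astype(np.int64), 0, size - 1)
        i1 = np.clip(i0 + 1, 0, size - 1)
        t = np.clip(src - np.floor(src), 0.0, 1.0)
        t[src < 0] = 0.0
        return i0, i1, t.astype(np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        r0, r1, tr = self._plan(h)
        c0, c1, tc = self._plan(w)
        self._cache = (x.shape, r0, r1, tr, c0, c1, tc)
        top = x[:, :, r0, :] * (1 - tr)[None, None, :, None] + x[:, :, r1, :] * tr[None, None, :, None]
        out = (
            top[:, :, :, c0] * (1 - tc)[None, None, None, :]
            + top[:, :, :, c1] * tc[None, None, None, :]
        )
        return out.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, c, h, w), r0, r1, tr, c0, c1, tc = self._cache
        dtop = np.zeros((dy.shape[0], dy.shape[1], 2 * h, w), dtype=np.float32)
        np.add.at(dtop, (slice(None), slice(None), slice(None), c0), dy * (1 - tc)[None, None, None, :])
        np.add.at(dtop, (slice(None), slice(None), slice(None), c1), dy * tc[None, None, None, :])
        dx = np.zeros((dy.shape[0], dy.shape[1], h, w), dtype=np.float32)
        np.add.at(dx, (slice(None), slice(None), r0, slice(None)), dtop * (1 - tr)[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), r1, slice(None)), dtop * tr[None, None, :, None])
        self._cache = None
        return dx

    def grads(self):
        return []


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, target: np.ndarray, weights: np.ndarray
):
    """Per-pixel weighted CE.

    logits (N, C, H, W); target (N, H, W) integer classes; weights (N, H, W).
    Returns (scalar loss, dlogits); the loss is the weight-normalized mean.
    """
    probs = softmax(logits, axis=1)
    n, c, h, w = logits.shape
    idx_n, idx_h, idx_w = np.ogrid[:n, :h, :w]
    p_true = probs[idx_n, target, idx_h, idx_w]
    wsum = float(weights.sum())
    loss = float((weights * -np.log(np.clip(p_true, 1e-12, None))).sum() / wsum)
    onehot = np.zeros_like(probs)
    onehot[idx_n, target, idx_h, idx_w] = 1.0
    dlogits = (probs - onehot) * (weights[:, None, :, :] / wsum)
    return loss, dlogits.astype(np.float32)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
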