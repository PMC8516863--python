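"""Minimal NumPy neural-network layers for the 2D CNN classifier.

Implements exactly what the classifier needs — 2D convolution (im2col /
matmul), batch normalisation, ReLU, 2x2 max pooling, inverted dropout, a
dense layer and softmax cross-entropy — with an Adam optimiser and Keras-
style L2 regularisation (lambda * sum(w^2) added to the loss, 2*lambda*w to
the gradient). Everything runs in float32, NHWC layout.

Convolution uses TensorFlow-style "same" padding (output spatial size
ceil(in / stride), extra padding on the bottom/right). The stride-1
backward pass is itself a convolution of the padded upstream gradient with
the flipped kernels, so it stays in matmul land; only strided convolutions
fall back to an index-scatter.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


def _same_pads(size: int, k: int, s: int) -> tuple[int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """x: (B, H, W, C) padded → columns (B, OH, OW, kh*kw*C)."""
    B, H, W, C = x.shape
    oh = (H - kh) // sh + 1
    ow = (W - kw) // sw + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    windows = windows[:, ::sh, ::sw]               # (B, oh, ow, C, kh, kw)
    cols = windows.transpose(0, 1, 2, 4, 5, 3)     # (B, oh, ow, kh, kw, C)
    return np.ascontiguousarray(cols).reshape(B, oh, ow, kh * kw * C)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, training):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError

    def reg_loss(self) -> float:
        return 0.0


class Conv2D(Layer):
    def __init__(self, c_in, c_out, kernel, stride=1, l2=0.0, rng=None):
        super().__init__()
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.kh, self.kw = kh, kw
        self.stride = (stride, stride) if np.isscalar(stride) else stride
        self.l2 = l2
        fan_in = kh * kw * c_in
        # He initialisation for ReLU stacks
        w = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.w = w.astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x, training):
        sh, sw = self.stride
        pt, pb = _same_pads(x.shape[1], self.kh, sh)
        pl, pr = _same_pads(x.shape[2], self.kw, sw)
        self._pads = (pt, pb, pl, pr)
        self._in_shape = x.shape
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = _im2col(xp, self.kh, self.kw, sh, sw)
        self._cols = cols
        out = cols @ self.w + self.b
        return out

    def backward(self, g):
        B, oh, ow, _ = g.shape
        gm = g.reshape(-1, self.c_out)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads[0][...] = (cols.T @ gm) + 2.0 * self.l2 * self.w
        self.grads[1][...] = gm.sum(axis=0) + 2.0 * self.l2 * self.b
        sh, sw = self.stride
        pt, pb, pl, pr = self._pads
        B_, H, W, C = self._in_shape
        # scatter the per-tap gradients back: kh*kw shifted adds
        dxp = np.zeros((B_, H + pt + pb, W + pl + pr, C), dtype=_F32)
        dcols = gm @ self.w.T  # (B*oh*ow, kh*kw*C)
        dcols = dcols.reshape(B, oh, ow, self.kh, self.kw, C)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + oh * sh:sh, j:j + ow * sw:sw] += dcols[:, :, :, i, j]
        dx = dxp[:, pt:pt + H, pl:pl + W]
        return np.ascontiguousarray(dx)

    def reg_loss(self):
        return float(self.l2 * (np.sum(self.w ** 2) + np.sum(self.b ** 2)))


class BatchNorm(Layer):
    """Channel-wise batch normalisation over (B, H, W) with running stats."""

    def __init__(self, c, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(c, dtype=_F32)
        self.run_var = np.ones(c, dtype=_F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(_F32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(_F32)
        else:
            mean, var = self.run_mean, self.run_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        self._xhat = (x - mean) * self._inv_std
        self._n = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        axes = tuple(range(g.ndim - 1))
        self.grads[0][...] = np.sum(g * self._xhat, axis=axes)
        self.grads[1][...] = np.sum(g, axis=axes)
        n = self._n
        gx = (self.gamma * self._inv_std / n) * (
            n * g - np.sum(g, axis=axes)
            - self._xhat * np.sum(g * self._xhat, axis=axes)
        )
        return gx.astype(_F32)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x, training):
        B, H, W, C = x.shape
        xr = x.reshape(B, H // 2, 2, W // 2, 2, C)
        out = xr.max(axis=(2, 4))
        self._mask = (xr == out[:, :, None, :, None, :])
        return out

    def backward(self, g):
        gexp = g[:, :, None, :, None, :] * self._mask
        B, oh, _, ow, _, C = gexp.shape
        return gexp.reshape(B, oh * 2, ow * 2, C)


class Dropout(Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, rng, l2=0.0):
        super().__init__()
        self.w = (rng.standard_normal((d_in, d_out))
                  * np.sqrt(2.0 / d_in)).astype(_F32)
        self.b = np.zeros(d_out, dtype=_F32)
        self.l2 = l2
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g + 2.0 * self.l2 * self.w
        self.grads[1][...] = g.sum(axis=0) + 2.0 * self.l2 * self.b
        return g @ self.w.T

    def reg_loss(self):
        return float(self.l2 * (np.sum(self.w ** 2) + np.sum(self.b ** 2)))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Sparse categorical cross-entropy; returns (mean loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None))))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(_F32)


class Adam:
    def __init__(self, params, grads, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self):
        return [g for lay in self.layers for g in lay.grads]

    def forward(self, x, training=False):
        for lay in self.layers:
            x = lay.forward(x, training)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def reg_loss(self) -> float:
        return sum(lay.reg_loss() for lay in self.layers)

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def state(self) -> list[np.ndarray]:
        out = [p.copy() for p in self.params]
        for lay in self.layers:
            if isinstance(lay, BatchNorm):
                out += [lay.run_mean.copy(), lay.run_var.copy()]
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        k = 0
        for p in self.params:
            p[...] = state[k]
            k += 1
        for lay in self.layers:
            if isinstance(lay, BatchNorm):
                lay.run_mean = state[k].copy()
                lay.run_var = state[k + 1].copy()
                k += 2
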