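"""Minimal 3D convolutional network primitives in numpy.

Layers operate on channels-last volumes ``(X, Y, Z, C)`` and implement both
forward and backward passes explicitly; gradients are verified against
finite differences in the test suite. Only what the segmentation U-Net
needs is provided: 3x3x3 same-padding convolution (via im2col), ReLU,
2x2x2/stride-2 max pooling, 2x2x2/stride-2 transposed convolution (whose
stride equals its kernel, so contributions never overlap), channel
concatenation, 1x1x1 convolution, and softmax cross-entropy. Optimization
is Adam with the standard bias correction.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


# ---------------------------------------------------------------------------
# conv 3x3x3, stride 1, same padding


def _im2col(x: np.ndarray) -> np.ndarray:
    """(X,Y,Z,C) -> (X*Y*Z, 27*C) patch matrix with 1-voxel zero padding."""
    X, Y, Z, C = x.shape
    xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(0, 1, 2))
    # win: (X, Y, Z, C, 3, 3, 3) -> (XYZ, 3,3,3,C) -> flat
    win = np.moveaxis(win, 3, 6)  # (X,Y,Z,3,3,3,C)
    return np.ascontiguousarray(win).reshape(X * Y * Z, 27 * C)


class Conv3x3:
    """3x3x3 convolution, stride 1, zero same-padding, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = he_init(rng, (27 * c_in, c_out), fan_in=27 * c_in)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._cols = None
        self._shape = None

    def forward(self, x: np.ndarray, retain: bool = True) -> np.ndarray:
        cols = _im2col(x)
        if retain:  # backward needs the patch matrix; inference skips it
            self._shape = x.shape
            self._cols = cols
        X, Y, Z, _ = x.shape
        return (cols @ self.w + self.b).reshape(X, Y, Z, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        X, Y, Z, C = self._shape
        dyf = dy.reshape(-1, dy.shape[-1])
        self.grads[0] += self._cols.T @ dyf
        self.grads[1] += dyf.sum(axis=0)
        # dx: correlate dy with the spatially flipped kernel (full = same here)
        w = self.w.reshape(3, 3, 3, C, -1)
        w_flip = w[::-1, ::-1, ::-1]                 # flip spatial axes
        w_t = np.swapaxes(w_flip, 3, 4)              # (3,3,3,C_out,C_in)
        cols_dy = _im2col(dy)
        dx = cols_dy @ w_t.reshape(-1, C)
        return dx.reshape(X, Y, Z, C)


class Conv1x1:
    """1x1x1 convolution (per-voxel linear map) with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = he_init(rng, (c_in, c_out), fan_in=c_in)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf = self._x.reshape(-1, self._x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.grads[0] += xf.T @ dyf
        self.grads[1] += dyf.sum(axis=0)
        return (dyf @ self.w.T).reshape(self._x.shape)


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2x2 max pooling with stride 2. Ties route the gradient to the
    first window position (fixed order), keeping backward deterministic."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        X, Y, Z, C = x.shape
        w = x.reshape(X // 2, 2, Y // 2, 2, Z // 2, 2, C)
        w = np.moveaxis(w, (1, 3, 5), (3, 4, 5))       # (X/2,Y/2,Z/2,2,2,2,C)
        flat = w.reshape(X // 2, Y // 2, Z // 2, 8, C)
        self._arg = flat.argmax(axis=3)                # first max on ties
        self._inshape = x.shape
        return flat.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        Xh, Yh, Zh, C = dy.shape
        flat = np.zeros((Xh, Yh, Zh, 8, C), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        w = flat.reshape(Xh, Yh, Zh, 2, 2, 2, C)
        w = np.moveaxis(w, (3, 4, 5), (1, 3, 5))
        return w.reshape(self._inshape)


class Deconv2:
    """2x2x2 transposed convolution with stride 2 (non-overlapping)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = he_init(rng, (2, 2, 2, c_in, c_out), fan_in=c_in)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        X, Y, Z, C = x.shape
        c_out = self.w.shape[-1]
        out = np.tensordot(x, self.w, axes=([3], [3]))  # (X,Y,Z,2,2,2,Cout)
        out = np.moveaxis(out, (3, 4, 5), (1, 3, 5))
        return out.reshape(2 * X, 2 * Y, 2 * Z, c_out) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        X, Y, Z, C = self._x.shape
        w = dy.reshape(X, 2, Y, 2, Z, 2, -1)
        w = np.moveaxis(w, (1, 3, 5), (3, 4, 5))        # (X,Y,Z,2,2,2,Cout)
        self.grads[0] += np.tensordot(self._x, w, axes=([0, 1, 2], [0, 1, 2]))\
            .transpose(1, 2, 3, 0, 4)
        self.grads[1] += dy.sum(axis=(0, 1, 2))
        return np.tensordot(w, self.w, axes=([3, 4, 5, 6], [0, 1, 2, 4]))


def softmax_cross_entropy(logits: np.ndarray, target_fg: np.ndarray
                          ) -> tuple[float, np.ndarray, np.ndarray]:
    """Per-voxel 2-class softmax + cross-entropy.

    ``logits`` is (X,Y,Z,2) (background, foreground); ``target_fg`` is the
    binary foreground mask. Returns (mean loss, foreground probability map,
    gradient w.r.t. logits).
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    sez = ez.sum(axis=-1, keepdims=True)
    p = ez / sez
    y = np.stack([1.0 - target_fg, target_fg], axis=-1)
    n = float(target_fg.size)
    # exact log-softmax (no clamping) so the loss value and the (p - y)/n
    # gradient stay consistent even with saturated logits
    logp = z - np.log(sez)
    loss = float(-(y * logp).sum() / n)
    dlogits = (p - y) / n
    return loss, p[..., 1], dlogits.astype(DTYPE)


class Adam:
    """Adam optimizer, beta1=0.9, beta2=0.999, eps=1e-8."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)
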