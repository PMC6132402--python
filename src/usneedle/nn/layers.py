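"""2D convolution / pooling / dense layers with explicit backprop.

Data layout is ``(N, C, H, W)`` float32.  Convolutions use im2col + BLAS
matmul; the col2im scatter in the backward pass loops over the (small) kernel
footprint with strided slice-adds, which is far faster than ``np.add.at``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """3×3 (or k×k) convolution, stride 1, 'valid' or 'same' zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same"):
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_channels))
        self.kernel = kernel
        self.padding = padding
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        if self.padding == "same":
            p = k // 2
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        n, c, hp, wp = xp.shape
        oh, ow = hp - k + 1, wp - k + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,OH,OW,k,k)
        # one 2D GEMM over all positions of all samples
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        wmat = self.weight.value.reshape(self.weight.value.shape[0], -1)
        y = cols @ wmat.T + self.bias.value
        self._cache = (cols, xp.shape, (oh, ow))
        return np.ascontiguousarray(y.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (oh, ow) = self._cache
        n, c, hp, wp = xp_shape
        k = self.kernel
        f = self.weight.value.shape[0]
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * oh * ow, f)
        wmat = self.weight.value.reshape(f, -1)
        self.weight.grad += (dyf.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dyf.sum(axis=0)
        # input grad via col2im
        dcols = (dyf @ wmat).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + oh, kj:kj + ow] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if self.padding == "same":
            p = k // 2
            return dxp[:, :, p:hp - p, p:wp - p]
        return dxp


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_features))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Dropout:
    """Inverted dropout; identity at inference.  ``p`` is the drop probability."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("drop probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool2d:
    """2×2 max pooling, stride 2, recording argmax indices for unpooling."""

    def __init__(self):
        self.indices = None  # (N, C, OH, OW) in {0..3}
        self._in_shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2d requires even spatial dims")
        oh, ow = h // 2, w // 2
        xr = x.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
        self.indices = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self.indices[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return max_unpool2d(dy, self.indices, self._in_shape)


def max_unpool2d(y: np.ndarray, indices: np.ndarray, out_shape) -> np.ndarray:
    """Place each pooled value back at its recorded argmax position (×2)."""
    n, c, oh, ow = y.shape
    out = np.zeros((n, c, oh, ow, 4), dtype=np.float32)
    np.put_along_axis(out, indices[..., None], y[..., None], axis=-1)
    out = out.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh * 2, ow * 2)
    return out[:, :, : out_shape[2], : out_shape[3]]


def max_unpool2d_backward(dy: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Gradient of :func:`max_unpool2d` w.r.t. its pooled input."""
    n, c, h, w = dy.shape
    oh, ow = h // 2, w // 2
    dyr = dy.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
    return np.take_along_axis(dyr, indices[..., None], axis=-1)[..., 0]


def nearest_upsample(x: np.ndarray, factor: int) -> np.ndarray:
    return x.repeat(factor, axis=2).repeat(factor, axis=3)


def nearest_upsample_backward(dy: np.ndarray, factor: int) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // factor, factor, w // factor, factor).sum(axis=(3, 5))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          axis: int = 1) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits.

    ``targets`` holds integer class labels with the class axis of ``logits``
    removed; the mean is over all remaining positions.
    """
    p = softmax(logits, axis=axis)
    pt = np.take_along_axis(p, np.expand_dims(targets, axis), axis=axis)
    loss = float(-np.log(np.clip(pt, 1e-12, None)).mean())
    grad = p.copy()
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, np.expand_dims(targets, axis), 1.0, axis=axis)
    grad -= onehot
    grad /= targets.size
    return loss, grad.astype(np.float32)
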