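"""3D convolutional layers with explicit forward/backward passes.

All tensors are ``(N, C, D, H, W)`` float32 arrays.  Convolutions use valid
padding only (no border padding), so spatial extents shrink by ``k - 1`` per
stride-1 layer; transposed convolutions invert the strided-shape arithmetic.
Forward passes are im2col + one BLAS matmul; backward passes reuse the same
column buffers, so cost is within a small constant of the forward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3D", "ConvTranspose3D", "conv_out_len", "conv_transpose_out_len"]


def conv_out_len(n: int, k: int, s: int) -> int:
    """Spatial output length of a valid convolution: floor((n - k)/s) + 1."""
    return (n - k) // s + 1


def conv_transpose_out_len(n: int, k: int, s: int) -> int:
    """Spatial output length of a transposed convolution: (n - 1)*s + k."""
    return (n - 1) * s + k


def _im2col(x: np.ndarray, k: int, stride: int):
    """Unfold ``x`` (N,C,D,H,W) into columns (N, Do*Ho*Wo, C*k^3)."""
    w = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    w = w[:, :, ::stride, ::stride, ::stride]
    n, c, do, ho, wo = w.shape[:5]
    cols = np.ascontiguousarray(w.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    return cols.reshape(n, do * ho * wo, c * k**3), (do, ho, wo)


def _col2im_add(gcols: np.ndarray, target_shape, k: int, stride: int, win_sp):
    """Scatter-add column gradients back onto the (N,C,D,H,W) input grid.

    Inverse of :func:`_im2col`: each of the k^3 kernel offsets contributes a
    strided slice-add, so overlapping windows accumulate.
    """
    n, c, d, h, w = target_shape
    do, ho, wo = win_sp
    g = np.zeros(target_shape, dtype=gcols.dtype)
    gc = gcols.reshape(n, do, ho, wo, c, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
    s = stride
    for i in range(k):
        for j in range(k):
            for l in range(k):
                g[:, :, i : i + s * do : s, j : j + s * ho : s, l : l + s * wo : s] += gc[
                    ..., i, j, l
                ]
    return g


class Conv3D:
    """Strided valid 3D convolution with optional ReLU, trainable W and b."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 relu: bool = True, rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.k, self.stride, self.relu = c_in, c_out, kernel, stride, relu
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        # He fan-in scaling keeps ReLU pre-activations at unit variance
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kernel, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def out_shape(self, sp):
        return tuple(conv_out_len(n, self.k, self.stride) for n in sp)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, sp = _im2col(x, self.k, self.stride)
        wm = self.W.reshape(self.c_out, -1)
        y = cols @ wm.T + self.b
        y = y.transpose(0, 2, 1).reshape(x.shape[0], self.c_out, *sp)
        neg = None
        if self.relu:
            neg = y < 0
            y = np.where(neg, np.float32(0.0), y)
        if train:
            self._cache = (cols, x.shape, sp, neg)
        return y

    def backward(self, gy: np.ndarray):
        cols, x_shape, sp, neg = self._cache
        if neg is not None:
            gy = np.where(neg, np.float32(0.0), gy)
        n = gy.shape[0]
        gyf = gy.reshape(n, self.c_out, -1).transpose(0, 2, 1)  # (N, V, Co)
        self.gb = gyf.sum(axis=(0, 1))
        gW = np.einsum("nvo,nvc->oc", gyf, cols, optimize=True)
        self.gW = gW.reshape(self.W.shape)
        gcols = gyf @ self.W.reshape(self.c_out, -1)
        return _col2im_add(gcols, x_shape, self.k, self.stride, sp)

    def params_grads(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ConvTranspose3D:
    """Strided 3D transposed convolution (learnable upsampling) with ReLU."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 2,
                 relu: bool = True, rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.k, self.stride, self.relu = c_in, c_out, kernel, stride, relu
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3 / stride**3  # each output voxel sees ~k^3/s^3 inputs
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_in, c_out, kernel, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def out_shape(self, sp):
        return tuple(conv_transpose_out_len(n, self.k, self.stride) for n in sp)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, _, d, h, w = x.shape
        osp = self.out_shape((d, h, w))
        xf = x.reshape(n, self.c_in, -1).transpose(0, 2, 1)  # (N, V, Ci)
        gcols = xf @ self.W.reshape(self.c_in, -1)  # (N, V, Co*k^3)
        y = _col2im_add(gcols, (n, self.c_out, *osp), self.k, self.stride, (d, h, w))
        y += self.b[None, :, None, None, None]
        neg = None
        if self.relu:
            neg = y < 0
            y = np.where(neg, np.float32(0.0), y)
        if train:
            self._cache = (xf, (d, h, w), neg)
        return y

    def backward(self, gy: np.ndarray):
        xf, sp, neg = self._cache
        if neg is not None:
            gy = np.where(neg, np.float32(0.0), gy)
        self.gb = gy.sum(axis=(0, 2, 3, 4))
        cols, _ = _im2col(gy, self.k, self.stride)  # windows of gy == forward scatter targets
        gW = np.einsum("nvc,nvk->ck", xf, cols, optimize=True)
        self.gW = gW.reshape(self.W.shape)
        gx = cols @ self.W.reshape(self.c_in, -1).T  # (N, V, Ci)
        n = gy.shape[0]
        return np.ascontiguousarray(gx.transpose(0, 2, 1)).reshape(n, self.c_in, *sp)

    def params_grads(self):
        return [(self.W, self.gW), (self.b, self.gb)]
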