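"""Minimal CNN layer primitives with explicit forward/backward passes.

Every layer's ``forward`` returns ``(output, cache)``; ``backward`` consumes
that cache, fills ``self.grads`` for its parameters and returns the gradient
with respect to its input.  Explicit backprop (rather than a third-party
autodiff graph) is what gives the explanation methods uniform access to
per-layer activations, class-score gradients and the guided-ReLU backward
variant.

Convolution is evaluated as a batched matrix product over im2col patches;
the backward scatter to image space (col2im) accumulates per kernel offset
with strided slice additions.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

Array = np.ndarray

def _out_hw(H: int, W: int, KH: int, KW: int, stride: int, pad: int) -> Tuple[int, int]:
    OH = (H + 2 * pad - KH) // stride + 1
    OW = (W + 2 * pad - KW) // stride + 1
    if OH < 1 or OW < 1:
        raise ValueError("convolution output would have spatial size < 1")
    return OH, OW


def im2col(x: Array, KH: int, KW: int, stride: int, pad: int) -> Tuple[Array, Tuple[int, int]]:
    """Patches of ``x`` as a (N, C*KH*KW, OH*OW) matrix (row order c, p, q)."""
    N, C, H, W = x.shape
    OH, OW = _out_hw(H, W, KH, KW, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (KH, KW), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, KH, KW)
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        N, C * KH * KW, OH * OW
    )
    return cols, (OH, OW)


def col2im(dcols: Array, xshape: tuple, KH: int, KW: int, stride: int, pad: int) -> Array:
    """Scatter-add column gradients back to image space (inverse of im2col)."""
    N, C, H, W = xshape
    OH, OW = _out_hw(H, W, KH, KW, stride, pad)
    d = dcols.reshape(N, C, KH, KW, OH, OW)
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    for p in range(KH):
        for q in range(KW):
            dxp[:, :, p : p + stride * OH : stride, q : q + stride * OW : stride] += d[
                :, :, p, q
            ]
    return dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp


class Layer:
    """Base layer; subclasses define forward/backward and optional params."""

    def __init__(self) -> None:
        self.params: Dict[str, Array] = {}
        self.grads: Dict[str, Array] = {}

    def forward(self, x: Array) -> Tuple[Array, object]:
        raise NotImplementedError

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        raise NotImplementedError

    def param_items(self) -> Iterator[Tuple["Layer", str]]:
        for name in self.params:
            yield self, name

    def out_spatial(self, h: int, w: int) -> Tuple[int, int]:
        return h, w


class Conv2D(Layer):
    """2-D convolution (cross-correlation) with 'same'-style padding by default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        pad: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        super().__init__()
        self.stride = int(stride)
        self.pad = kernel // 2 if pad is None else int(pad)
        rng = np.random.default_rng(0) if rng is None else rng
        scale = np.sqrt(2.0 / (in_channels * kernel * kernel))  # He init
        self.params = {
            "W": rng.standard_normal((out_channels, in_channels, kernel, kernel)) * scale,
            "b": np.zeros(out_channels),
        }

    def out_spatial(self, h: int, w: int) -> Tuple[int, int]:
        k = self.params["W"].shape[2]
        return (
            (h + 2 * self.pad - k) // self.stride + 1,
            (w + 2 * self.pad - k) // self.stride + 1,
        )

    def forward(self, x: Array) -> Tuple[Array, object]:
        W, b = self.params["W"], self.params["b"]
        F, _, KH, KW = W.shape
        N = x.shape[0]
        cols, (OH, OW) = im2col(x, KH, KW, self.stride, self.pad)
        out = np.matmul(W.reshape(F, -1), cols)  # (N, F, OH*OW)
        out = out.reshape(N, F, OH, OW) + b[None, :, None, None]
        return out, (x.shape, cols)

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        xshape, cols = cache
        W = self.params["W"]
        F, _, KH, KW = W.shape
        N = xshape[0]
        dout2 = dout.reshape(N, F, -1)
        self.grads["b"] = dout2.sum(axis=(0, 2))
        # dW as one GEMM: (F, N*L) @ (N*L, K)
        dflat = np.ascontiguousarray(dout2.transpose(1, 0, 2)).reshape(F, -1)
        cflat = np.ascontiguousarray(cols.transpose(0, 2, 1)).reshape(-1, cols.shape[1])
        self.grads["W"] = (dflat @ cflat).reshape(W.shape)
        dcols = np.matmul(W.reshape(F, -1).T, dout2)
        return col2im(dcols, xshape, KH, KW, self.stride, self.pad)


class ReLU(Layer):
    """Rectified linear unit; supports the guided-backprop backward variant.

    In guided mode the backward pass transmits gradient only where the forward
    input was positive *and* the incoming gradient is positive.
    """

    def forward(self, x: Array) -> Tuple[Array, object]:
        mask = x > 0
        return x * mask, mask

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        dx = dout * cache
        if guided:
            dx = dx * (dout > 0)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling; ties resolve to the first (row-major) maximum."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = int(size)

    def out_spatial(self, h: int, w: int) -> Tuple[int, int]:
        if h % self.size or w % self.size:
            raise ValueError(f"spatial size ({h},{w}) not divisible by pool {self.size}")
        return h // self.size, w // self.size

    def forward(self, x: Array) -> Tuple[Array, object]:
        N, C, H, W = x.shape
        s = self.size
        OH, OW = self.out_spatial(H, W)
        xr = x.reshape(N, C, OH, s, OW, s).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, OH, OW, s * s)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        return out, (x.shape, idx)

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        xshape, idx = cache
        N, C, H, W = xshape
        s = self.size
        OH, OW = H // s, W // s
        dxr = np.zeros((N, C, OH, OW, s * s), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        return dxr.reshape(N, C, OH, OW, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(xshape)


class Flatten(Layer):
    def forward(self, x: Array) -> Tuple[Array, object]:
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        return dout.reshape(cache)


class GlobalAvgPool(Layer):
    """Spatial mean per feature map: (N, C, H, W) -> (N, C)."""

    def forward(self, x: Array) -> Tuple[Array, object]:
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        N, C, H, W = cache
        return np.broadcast_to(dout[:, :, None, None], cache) / (H * W)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        rng = np.random.default_rng(0) if rng is None else rng
        scale = np.sqrt(2.0 / in_features)
        self.params = {
            "W": rng.standard_normal((in_features, out_features)) * scale,
            "b": np.zeros(out_features),
        }

    def forward(self, x: Array) -> Tuple[Array, object]:
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        x = cache
        self.grads["W"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ResidualBlock(Layer):
    """conv-ReLU-conv residual branch added to a (possibly projected) skip path.

    With an all-zero second convolution the branch vanishes and, because the
    block input is non-negative (post-ReLU), the output ReLU reduces to the
    identity on the skip path.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        self.conv1 = Conv2D(in_channels, out_channels, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(out_channels, out_channels, 3, stride=1, rng=rng)
        self.proj: Optional[Conv2D] = None
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv2D(in_channels, out_channels, 1, stride=stride, pad=0, rng=rng)
        self.relu_out = ReLU()

    def out_spatial(self, h: int, w: int) -> Tuple[int, int]:
        return self.conv1.out_spatial(h, w)

    def param_items(self):
        for sub in (self.conv1, self.conv2, self.proj):
            if sub is not None:
                yield from sub.param_items()

    def forward(self, x: Array) -> Tuple[Array, object]:
        h1, c1 = self.conv1.forward(x)
        a1, m1 = self.relu1.forward(h1)
        h2, c2 = self.conv2.forward(a1)
        if self.proj is not None:
            skip, cp = self.proj.forward(x)
        else:
            skip, cp = x, None
        out, mo = self.relu_out.forward(h2 + skip)
        return out, (c1, m1, c2, cp, mo)

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        c1, m1, c2, cp, mo = cache
        dsum = self.relu_out.backward(dout, mo, guided=guided)
        da1 = self.conv2.backward(dsum, c2)
        dh1 = self.relu1.backward(da1, m1, guided=guided)
        dx = self.conv1.backward(dh1, c1)
        if self.proj is not None:
            dx = dx + self.proj.backward(dsum, cp)
        else:
            dx = dx + dsum
        return dx


class ResidualStage(Layer):
    """A sequence of residual blocks; the first may downsample/widen."""

    def __init__(self, blocks: List[ResidualBlock]) -> None:
        super().__init__()
        self.blocks = blocks

    def out_spatial(self, h: int, w: int) -> Tuple[int, int]:
        for b in self.blocks:
            h, w = b.out_spatial(h, w)
        return h, w

    def param_items(self):
        for b in self.blocks:
            yield from b.param_items()

    def forward(self, x: Array) -> Tuple[Array, object]:
        caches = []
        for b in self.blocks:
            x, c = b.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dout: Array, cache: object, guided: bool = False) -> Array:
        for b, c in zip(reversed(self.blocks), reversed(cache)):
            dout = b.backward(dout, c, guided=guided)
        return dout
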