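"""Differentiable layers with explicit forward/backward passes.

All tensors are ``float32`` with layout ``(N, C, *spatial)``; ``ndim`` below
always refers to the number of spatial dimensions (2 or 3).  Convolutions
are evaluated by materializing sliding windows (im2col) and dispatching to
BLAS; their input gradient is reassembled with one strided accumulation per
kernel offset.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "ConvND", "TransposedConvND", "InstanceNorm", "LeakyReLU", "AvgPool"]


class Layer:
    """Base class: parameter/gradient dictionaries plus train/eval mode."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _corr_valid(x: np.ndarray, w: np.ndarray, nd: int) -> np.ndarray:
    """Valid-mode stride-1 correlation of (N, C_in, *S) with (C_out, C_in, *k)."""
    k = w.shape[2]
    win = sliding_window_view(x, (k,) * nd, axis=tuple(range(2, 2 + nd)))
    out_spatial = win.shape[2 : 2 + nd]
    order = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    cols = np.ascontiguousarray(win.transpose(order), dtype=np.float32)
    cols = cols.reshape(-1, x.shape[1] * k**nd)
    y = cols @ w.reshape(w.shape[0], -1).T
    y = y.reshape((x.shape[0],) + out_spatial + (w.shape[0],))
    return np.ascontiguousarray(np.moveaxis(y, -1, 1))


class ConvND(Layer):
    """k^d convolution with zero padding and optional stride."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        ndim: int,
        kernel: int = 3,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.cin, self.cout, self.ndim = in_channels, out_channels, ndim
        self.k, self.s = kernel, stride
        self.pad = kernel // 2
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**ndim
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels) + (kernel,) * ndim)
        self.params["w"] = w.astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        nd, k, s, p = self.ndim, self.k, self.s, self.pad
        pads = [(0, 0), (0, 0)] + [(p, p)] * nd
        xp = np.pad(x, pads) if p else x
        self._xpad_shape = xp.shape
        win = sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, 2 + nd)))
        if s > 1:
            sl = (slice(None), slice(None)) + (slice(None, None, s),) * nd + (slice(None),) * nd
            win = win[sl]
        # (N, C_in, *S_out, *k) -> (N, *S_out, C_in, *k) -> (M, C_in*k^d)
        self._out_spatial = win.shape[2 : 2 + nd]
        order = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
        cols = np.ascontiguousarray(win.transpose(order), dtype=np.float32)
        M = int(np.prod((x.shape[0],) + self._out_spatial))
        cols = cols.reshape(M, self.cin * k**nd)
        if train:
            self._cols = cols
            self._n = x.shape[0]
        wmat = self.params["w"].reshape(self.cout, -1)
        y = cols @ wmat.T + self.params["b"]
        y = y.reshape((x.shape[0],) + self._out_spatial + (self.cout,))
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd, k, s, p = self.ndim, self.k, self.s, self.pad
        dyc = np.moveaxis(dy, 1, -1).reshape(-1, self.cout).astype(np.float32)
        self.grads["w"] += (dyc.T @ self._cols).reshape(self.params["w"].shape)
        self.grads["b"] += dyc.sum(axis=0)
        del self._cols
        # input gradient = correlation of the (stride-dilated) output gradient
        # with the spatially flipped, channel-swapped kernel
        xpad_spatial = self._xpad_shape[2:]
        if s > 1:
            dil = np.zeros(dy.shape[:2] + tuple(s * (o - 1) + 1 for o in self._out_spatial),
                           dtype=np.float32)
            dil[(slice(None), slice(None)) + (slice(None, None, s),) * nd] = dy
        else:
            dil = np.ascontiguousarray(dy, dtype=np.float32)
        pads = [(0, 0), (0, 0)]
        for sp, dl in zip(xpad_spatial, dil.shape[2:]):
            pads.append((k - 1, k - 1 + sp - dl - (k - 1)))
        z = np.pad(dil, pads)
        wflip = self.params["w"][(slice(None), slice(None)) + (slice(None, None, -1),) * nd]
        wswap = np.ascontiguousarray(np.swapaxes(wflip, 0, 1))  # (C_in, C_out, *k)
        dxp = _corr_valid(z, wswap, nd)
        if p:
            core = (slice(None), slice(None)) + (slice(p, -p),) * nd
            dxp = np.ascontiguousarray(dxp[core])
        return dxp


class TransposedConvND(Layer):
    """2x upsampling transposed convolution (kernel = stride = 2)."""

    def __init__(self, in_channels: int, out_channels: int, ndim: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.cin, self.cout, self.ndim = in_channels, out_channels, ndim
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_channels, out_channels) + (2,) * ndim)
        self.params["w"] = w.astype(np.float32)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        nd = self.ndim
        if train:
            self._x = x
        t = np.tensordot(x, self.params["w"], axes=([1], [0]))  # (N, *S, C_out, *2)
        n, spatial = x.shape[0], x.shape[2:]
        out = np.zeros((n, self.cout) + tuple(2 * s for s in spatial), dtype=np.float32)
        t = np.moveaxis(t, 1 + nd, 1)  # (N, C_out, *S, *2)
        for off in itertools.product(range(2), repeat=nd):
            dst = (slice(None), slice(None)) + tuple(slice(o, None, 2) for o in off)
            out[dst] = t[(Ellipsis,) + off]
        out += self.params["b"].reshape((1, -1) + (1,) * nd)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = self.ndim
        x = self._x
        n, spatial = x.shape[0], x.shape[2:]
        t = np.empty((n, self.cout) + tuple(spatial) + (2,) * nd, dtype=np.float32)
        for off in itertools.product(range(2), repeat=nd):
            src = (slice(None), slice(None)) + tuple(slice(o, None, 2) for o in off)
            t[(Ellipsis,) + off] = dy[src]
        self.grads["b"] += dy.sum(axis=(0,) + tuple(range(2, 2 + nd)))
        tt = np.moveaxis(t, 1, 1 + nd)  # (N, *S, C_out, *2)
        ax_x = [0] + list(range(2, 2 + nd))
        ax_t = [0] + list(range(1, 1 + nd))
        self.grads["w"] += np.tensordot(x, tt, axes=(ax_x, ax_t)).astype(np.float32)
        dx = np.tensordot(tt, self.params["w"], axes=(list(range(1 + nd, 1 + 2 * nd + 1)),
                                                      list(range(1, 2 + nd))))
        del self._x
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels: int, ndim: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.ndim, self.eps = ndim, eps
        self.params["g"] = np.ones(channels, dtype=np.float32)
        self.params["b"] = np.zeros(channels, dtype=np.float32)
        self.zero_grad()

    def _bc(self, v: np.ndarray) -> np.ndarray:
        return v.reshape((1, -1) + (1,) * self.ndim)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(2, 2 + self.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        if train:
            self._xhat, self._std = xhat, std
        return self._bc(self.params["g"]) * xhat + self._bc(self.params["b"])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, 2 + self.ndim))
        m = float(np.prod(dy.shape[2:]))
        xhat, std = self._xhat, self._std
        sum_axes = (0,) + axes
        self.grads["g"] += (dy * xhat).sum(axis=sum_axes)
        self.grads["b"] += dy.sum(axis=sum_axes)
        dxhat = dy * self._bc(self.params["g"])
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)) / std
        del self._xhat, self._std
        return dx.astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._neg = x < 0
        return np.where(x < 0, self.slope * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._neg, self.slope * dy, dy)
        del self._neg
        return dx.astype(np.float32)


class AvgPool(Layer):
    """Factor-2 average pooling over all spatial axes (sizes must be even)."""

    def __init__(self, ndim: int) -> None:
        super().__init__()
        self.ndim = ndim

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        nd = self.ndim
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"AvgPool requires even spatial sizes, got {x.shape[2:]}")
        shape: list[int] = list(x.shape[:2])
        for s in x.shape[2:]:
            shape += [s // 2, 2]
        xr = x.reshape(shape)
        axes = tuple(3 + 2 * i for i in range(nd))
        self._in_shape = x.shape
        return xr.mean(axis=axes).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = self.ndim
        scale = 1.0 / (2**nd)
        out = dy * scale
        for ax in range(2, 2 + nd):
            out = np.repeat(out, 2, axis=ax)
        return np.ascontiguousarray(out, dtype=np.float32)
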