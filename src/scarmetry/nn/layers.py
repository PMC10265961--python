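"""Layer primitives with analytic forward/backward passes.

Tensors are NCHW float64. Each layer caches what its backward pass needs on
forward; ``backward`` consumes the upstream gradient, fills ``self.grads``
(same keys as ``self.params``) and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid", "UpsampleNearest2d"]


class Layer:
    """Base class: parameter/gradient dictionaries and the train/eval flag."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """2D convolution via im2col. 'same'-style symmetric zero padding of
    ``(k - 1) // 2`` unless overridden."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.stride = stride
        self.padding = (k - 1) // 2 if padding is None else padding
        self.k = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * k * k
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, k, k))
        self.grads["W"] = np.zeros_like(self.params["W"])
        if bias:
            self.params["b"] = np.zeros(out_channels)
            self.grads["b"] = np.zeros_like(self.params["b"])
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, Ho, Wo, k, k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        Wm = self.params["W"].reshape(self.out_channels, -1)
        out = cols @ Wm.T
        if "b" in self.params:
            out += self.params["b"]
        out = out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)
        if training:
            self._cache = (cols, x.shape, (ho, wo))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.padding
        dm = dout.transpose(0, 2, 3, 1).reshape(-1, self.out_channels)
        self.grads["W"] += (dm.T @ cols).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] += dm.sum(axis=0)
        dcols = dm @ self.params["W"].reshape(self.out_channels, -1)
        dwin = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dwin[:, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.grads["gamma"] = np.zeros(channels)
        self.grads["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]
        if training:
            self._cache = (xhat, inv_std, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        # standard batchnorm backward over the (N,H,W) reduction axes
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        if training:
            self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class UpsampleNearest2d(Layer):
    def __init__(self, scale: int = 2) -> None:
        super().__init__()
        self.scale = scale

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = self.scale
        return x.repeat(s, axis=2).repeat(s, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self.scale
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // s, s, w // s, s).sum(axis=(3, 5))


class UpsampleBilinear2d(Layer):
    """2x bilinear upsampling (half-pixel centre alignment): each output
    sample mixes its two bracketing inputs with weights 3/4 and 1/4, per
    axis. Used for the final upsample so that thresholded masks are not
    quantized to 2x2 blocks."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._in_shape = x.shape
        return self._interp(x)

    @staticmethod
    def _interp(x: np.ndarray) -> np.ndarray:
        xe = np.pad(x, ((0, 0), (0, 0), (1, 1), (0, 0)), mode="edge")
        h = x.shape[2]
        rows_a = 0.25 * xe[:, :, 0:h, :] + 0.75 * xe[:, :, 1 : h + 1, :]
        rows_b = 0.75 * xe[:, :, 1 : h + 1, :] + 0.25 * xe[:, :, 2 : h + 2, :]
        y = np.stack([rows_a, rows_b], axis=3).reshape(
            x.shape[0], x.shape[1], 2 * h, x.shape[3]
        )
        ye = np.pad(y, ((0, 0), (0, 0), (0, 0), (1, 1)), mode="edge")
        w = x.shape[3]
        cols_a = 0.25 * ye[:, :, :, 0:w] + 0.75 * ye[:, :, :, 1 : w + 1]
        cols_b = 0.75 * ye[:, :, :, 1 : w + 1] + 0.25 * ye[:, :, :, 2 : w + 2]
        return np.stack([cols_a, cols_b], axis=4).reshape(
            y.shape[0], y.shape[1], y.shape[2], 2 * w
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dout.shape
        h, w = h2 // 2, w2 // 2
        # adjoint of the column interpolation
        d = dout.reshape(n, c, h2, w, 2)
        da, db = d[..., 0], d[..., 1]
        dye = np.zeros((n, c, h2, w + 2))
        dye[:, :, :, 0:w] += 0.25 * da
        dye[:, :, :, 1 : w + 1] += 0.75 * da + 0.75 * db
        dye[:, :, :, 2 : w + 2] += 0.25 * db
        dy = dye[:, :, :, 1 : w + 1]
        dy[:, :, :, 0] += dye[:, :, :, 0]      # edge padding folds back
        dy[:, :, :, -1] += dye[:, :, :, w + 1]
        # adjoint of the row interpolation
        d = dy.reshape(n, c, h, 2, w)
        da, db = d[:, :, :, 0], d[:, :, :, 1]
        dxe = np.zeros((n, c, h + 2, w))
        dxe[:, :, 0:h] += 0.25 * da
        dxe[:, :, 1 : h + 1] += 0.75 * da + 0.75 * db
        dxe[:, :, 2 : h + 2] += 0.25 * db
        dx = dxe[:, :, 1 : h + 1]
        dx[:, :, 0] += dxe[:, :, 0]
        dx[:, :, -1] += dxe[:, :, h + 1]
        return dx
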