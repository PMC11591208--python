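"""Core layers with explicit forward/backward passes.

All arrays are float32; image tensors are (N, C, H, W), token tensors are
(N, T, D).  Layers cache what their backward pass needs during forward;
``backward`` consumes the upstream gradient and both accumulates parameter
gradients and returns the input gradient.
"""

from __future__ import annotations

import numpy as np

_SQRT_2_OVER_PI = np.float32(np.sqrt(2.0 / np.pi))


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Module:
    """Minimal layer base: forward/backward plus parameter traversal."""

    training: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def children(self) -> list["Module"]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(c for c in v if isinstance(c, Module))
        return out

    def parameters(self) -> list[Parameter]:
        own = [v for v in self.__dict__.values() if isinstance(v, Parameter)]
        for child in self.children():
            own.extend(child.parameters())
        return own

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for child in self.children():
            child.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        """Arrays that define the model (parameters + buffers), for copy/restore.

        Collected recursively so that layer overrides (e.g. batch-norm
        running statistics) are included wherever the layer sits.
        """
        arrays = [v.data for v in self.__dict__.values() if isinstance(v, Parameter)]
        for child in self.children():
            arrays.extend(child.state_arrays())
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            dst[...] = src

    __call__ = None  # forward is explicit to keep tracing simple


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Conv2d(Module):
    """2D convolution (cross-correlation) via strided windows + einsum."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        # He-style init for ReLU nets
        std = np.sqrt(2.0 / (in_channels * k * k))
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, k, k)), "conv.weight"
        )
        self.bias = Parameter(np.zeros(out_channels), "conv.bias") if bias else None
        self.stride = stride
        self.padding = padding
        self.kernel_size = k
        self._xp: np.ndarray | None = None

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (self.kernel_size, self.kernel_size), axis=(2, 3)
        )
        return win[:, :, :: self.stride, :: self.stride]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        y = np.einsum(
            "nchwij,ocij->nohw", self._windows(xp), self.weight.data, optimize=True
        )
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        win = self._windows(xp)
        self.weight.grad += np.einsum("nohw,nchwij->ocij", dy, win, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dwin = np.einsum("nohw,ocij->nchwij", dy, self.weight.data, optimize=True)
        dxp = np.zeros_like(xp)
        s, k = self.stride, self.kernel_size
        ho, wo = dy.shape[2], dy.shape[3]
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dwin[..., i, j]
        p = self.padding
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(in_features, out_features)), "linear.weight"
        )
        self.bias = Parameter(np.zeros(out_features), "linear.bias") if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.weight.data
        if self.bias is not None:
            y += self.bias.data
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.weight.grad += x2.T @ dy2
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=0)
        return (dy @ self.weight.data.T).astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class GELU(Module):
    """Gaussian error linear unit (tanh approximation)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        u = _SQRT_2_OVER_PI * (x + 0.044715 * x**3)
        self._t = np.tanh(u)
        return (0.5 * x * (1.0 + self._t)).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, t = self._x, self._t
        du = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x**2)
        grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * du
        return (dy * grad).astype(np.float32)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        return (dy * y * (1.0 - y)).astype(np.float32)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def state_arrays(self) -> list[np.ndarray]:
        return [self.gamma.data, self.beta.data, self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * self._xhat
        y += self.beta.data[None, :, None, None]
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        xhat = self._xhat
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g_over_std = (self.gamma.data / self._std)[None, :, None, None]
        if not self.training:
            return (dy * g_over_std).astype(np.float32)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        mean_dy = dy.mean(axis=axes)[None, :, None, None]
        mean_dy_xhat = (dy * xhat).mean(axis=axes)[None, :, None, None]
        return (g_over_std * (dy - mean_dy - xhat * mean_dy_xhat)).astype(np.float32)


class LayerNorm(Module):
    """Normalization over the last axis (token feature dimension)."""

    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(dim), "ln.gamma")
        self.beta = Parameter(np.zeros(dim), "ln.beta")
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = (x - mean) / self._std
        return (self.gamma.data * self._xhat + self.beta.data).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        red = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=red)
        self.beta.grad += dy.sum(axis=red)
        g = dy * self.gamma.data
        mean_g = g.mean(axis=-1, keepdims=True)
        mean_g_xhat = (g * xhat).mean(axis=-1, keepdims=True)
        return ((g - mean_g - xhat * mean_g_xhat) / self._std).astype(np.float32)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0) -> None:
        self.k = kernel_size
        self.s = stride or kernel_size
        self.p = padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.p
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        self._xp_shape = xp.shape
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.s, :: self.s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, self.k * self.k)
        self._argmax = flat.argmax(axis=-1)
        self._out_shape = (n, c, ho, wo)
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[
            ..., 0
        ].astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, ho, wo = self._out_shape
        dxp = np.zeros(self._xp_shape, dtype=np.float32)
        hi, wi = self._xp_shape[2], self._xp_shape[3]
        oi, oj = np.divmod(self._argmax, self.k)
        rows = (np.arange(ho)[None, None, :, None] * self.s + oi)
        cols = (np.arange(wo)[None, None, None, :] * self.s + oj)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, cols), dy)
        p = self.p
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return (
            dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(np.float32)
        )


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class GlobalAvgPool2d(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        scale = 1.0 / (h * w)
        return (
            np.broadcast_to(dy[:, :, None, None], dy.shape + (h, w)) * scale
        ).astype(np.float32)
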