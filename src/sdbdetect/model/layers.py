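"""NumPy layers with explicit forward/backward passes.

No deep-learning framework is available in the execution environment, so the
network is built from first principles: every layer caches what its backward
pass needs and exposes ``params`` / ``grads`` dictionaries keyed by array
name.  Shapes are (batch, time, features) throughout; pooling acts on the
time axis only.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

from ._recurrence import gru_backward, gru_forward


class Layer:
    kernel_names: tuple[str, ...] = ()

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Per-timestep affine map (B, T, D) -> (B, T, K)."""

    kernel_names = ("W",)

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        # variance-scaling (fan-in) initialization
        self.params["W"] = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(dtype)
        self.params["b"] = np.zeros(d_out, dtype)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        x = self._x
        B, T, D = x.shape
        self.grads["W"] = x.reshape(B * T, D).T @ dy.reshape(B * T, -1)
        self.grads["b"] = dy.sum(axis=(0, 1))
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool(Layer):
    """Stride-``k`` max pooling over the time axis (kernel = stride)."""

    def __init__(self, stride: int = 2):
        super().__init__()
        self.stride = stride

    def forward(self, x, train=False, rng=None):
        B, T, F = x.shape
        k = self.stride
        if T % k:
            raise ValueError(f"time length {T} not divisible by pool stride {k}")
        xr = x.reshape(B, T // k, k, F)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        B, T, F = self._shape
        k = self.stride
        dx = np.zeros((B, T // k, k, F), dtype=dy.dtype)
        idx = np.indices(self._arg.shape)
        dx[idx[0], idx[1], self._arg, idx[2]] = dy
        return dx.reshape(B, T, F)


class BatchNorm(Layer):
    """Feature-wise batch normalization over the (batch, time) axes."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.params["gamma"] = np.ones(n_features, dtype)
        self.params["beta"] = np.zeros(n_features, dtype)
        self.running_mean = np.zeros(n_features, dtype)
        self.running_var = np.ones(n_features, dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False, rng=None):
        if train:
            mu = x.mean(axis=(0, 1), dtype=x.dtype)
            var = x.var(axis=(0, 1), dtype=x.dtype)
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mu).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, train, x.shape[0] * x.shape[1])
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv, train, m = self._cache
        self.grads["gamma"] = np.sum(dy * xhat, axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        g = self.params["gamma"]
        if not train:
            return dy * g * inv
        dxhat = dy * g
        return (
            inv / m * (m * dxhat - dxhat.sum(axis=(0, 1)) - xhat * np.sum(dxhat * xhat, axis=(0, 1)))
        )


class GRU(Layer):
    """Single-direction GRU over (B, T, D) -> (B, T, H).

    Gate pre-activations: z = sig(xWz + hUz + bz), r = sig(xWr + hUr + br),
    n = tanh(xWn + r * (hUn) + bn), h' = (1 - z) * n + z * h.
    """

    kernel_names = ("W", "U")

    def __init__(self, d_in: int, units: int, rng: np.random.Generator, reverse: bool = False, dtype=np.float32):
        super().__init__()
        H = self.units = units
        self.reverse = reverse
        self.params["W"] = (rng.standard_normal((d_in, 3 * H)) * np.sqrt(1.0 / d_in)).astype(dtype)
        self.params["U"] = (rng.standard_normal((H, 3 * H)) * np.sqrt(1.0 / H)).astype(dtype)
        self.params["b"] = np.zeros(3 * H, dtype)

    def forward(self, x, train=False, rng=None):
        B, T, D = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        x = np.ascontiguousarray(x)
        gx = (x.reshape(B * T, D) @ W).reshape(B, T, 3 * H)
        gx += b
        out, Z, R, N, UN, HP = gru_forward(gx, U, self.reverse)
        self._cache = (x, Z, R, N, UN, HP)
        return out

    def backward(self, dy):
        x, Z, R, N, UN, HP = self._cache
        B, T, D = x.shape
        H = self.units
        Ut = np.ascontiguousarray(self.params["U"].T)
        dGx, dUin = gru_backward(np.ascontiguousarray(dy), Z, R, N, UN, HP, Ut, self.reverse)
        self.grads["W"] = x.reshape(B * T, D).T @ dGx.reshape(B * T, 3 * H)
        self.grads["U"] = HP.reshape(B * T, H).T @ dUin.reshape(B * T, 3 * H)
        self.grads["b"] = dGx.sum(axis=(0, 1))
        return (dGx.reshape(B * T, 3 * H) @ self.params["W"].T).reshape(B, T, D)


class BiGRU(Layer):
    """Bidirectional GRU; concatenates forward and time-reversed outputs."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fwd = GRU(d_in, units, rng, reverse=False, dtype=dtype)
        self.bwd = GRU(d_in, units, rng, reverse=True, dtype=dtype)
        self.units = units
        for tag, sub in (("f", self.fwd), ("b", self.bwd)):
            for k, v in sub.params.items():
                self.params[f"{tag}_{k}"] = v

    kernel_names = ("f_W", "f_U", "b_W", "b_U")

    def _sync(self) -> None:
        # params dict may have been replaced wholesale (checkpoint restore)
        for tag, sub in (("f", self.fwd), ("b", self.bwd)):
            for k in sub.params:
                sub.params[k] = self.params[f"{tag}_{k}"]

    def forward(self, x, train=False, rng=None):
        self._sync()
        hf = self.fwd.forward(x, train, rng)
        hb = self.bwd.forward(x, train, rng)
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy):
        H = self.units
        dxf = self.fwd.backward(dy[:, :, :H])
        dxb = self.bwd.backward(dy[:, :, H:])
        for tag, sub in (("f", self.fwd), ("b", self.bwd)):
            for k, v in sub.grads.items():
                self.grads[f"{tag}_{k}"] = v
        return dxf + dxb
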