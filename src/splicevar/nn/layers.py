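"""Neural-network layers with explicit forward/backward passes.

Sequence activations have shape (B, L, C): batch, sequence length,
channels. One-hot DNA input is (B, N, 4). Convolutions are stride-1 and
"valid" (no padding); the first convolution's channel axis is the full
4-nucleotide width, so a (k, 4) filter on an N x 4 matrix is a 1-D
convolution with 4 input channels. Max-pooling uses stride equal to pool
size and drops the remainder.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class; layers with parameters override ``params``/``grads``."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def init(self, rng: np.random.Generator) -> None:  # noqa: B027
        pass

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def out_shape(self, in_shape: tuple) -> tuple:
        """Output shape (without batch axis) given input shape."""
        return in_shape


class Conv1D(Layer):
    """Valid, stride-1 convolution along the sequence axis.

    Weights have shape (k, C_in, C_out). Output length is L - k + 1.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int):
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        self.W = np.zeros((kernel, in_channels, filters))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.kernel * self.in_channels
        self.W = glorot_uniform(rng, self.W.shape, fan_in, self.filters)
        self.b = np.zeros(self.filters)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] < self.kernel:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel {self.kernel}"
            )
        self._x = x
        # cols: (B, L', C_in, k)
        cols = sliding_window_view(x, self.kernel, axis=1)
        self._cols = cols
        return np.tensordot(cols, self.W, axes=([3, 2], [0, 1])) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # dW[t, c, o] = sum_{b,l} x[b, l+t, c] dy[b, l, o]
        dW = np.tensordot(self._cols, dy, axes=([0, 1], [0, 1]))  # (C, k, O)
        self.dW = dW.transpose(1, 0, 2)
        self.db = dy.sum(axis=(0, 1))
        # full correlation of dy with the flipped kernel recovers dx
        k = self.kernel
        pad = np.pad(dy, ((0, 0), (k - 1, k - 1), (0, 0)))
        win = sliding_window_view(pad, k, axis=1)  # (B, L, O, k)
        Wf = self.W[::-1]                          # (k, C, O)
        return np.tensordot(win, Wf, axes=([3, 2], [0, 2]))

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_shape(self, in_shape):
        L, C = in_shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        L_out = L - self.kernel + 1
        if L_out < 1:
            raise ValueError(
                f"kernel {self.kernel} does not fit input length {L}"
            )
        return (L_out, self.filters)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Max pooling along the sequence axis, stride = pool size."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, training=False):
        B, L, C = x.shape
        L_out = L // self.pool
        if L_out < 1:
            raise ValueError(f"pool {self.pool} does not fit length {L}")
        xt = x[:, :L_out * self.pool].reshape(B, L_out, self.pool, C)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        B, L, C = self._in_shape
        L_out = dy.shape[1]
        dxt = np.zeros((B, L_out, self.pool, C))
        np.put_along_axis(dxt, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C))
        dx[:, :L_out * self.pool] = dxt.reshape(B, L_out * self.pool, C)
        return dx

    def out_shape(self, in_shape):
        L, C = in_shape
        L_out = L // self.pool
        if L_out < 1:
            raise ValueError(f"pool {self.pool} does not fit length {L}")
        return (L_out, C)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 < rate < 1.0:
            raise ValueError(f"dropout rate must be in (0, 1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, in_features: int, units: int):
        self.in_features = in_features
        self.units = units
        self.W = np.zeros((in_features, units))
        self.b = np.zeros(units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def init(self, rng):
        self.W = glorot_uniform(rng, self.W.shape, self.in_features, self.units)
        self.b = np.zeros(self.units)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_shape(self, in_shape):
        return (self.units,)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _LSTMDirection:
    """One direction of an LSTM; gate order (i, f, g, o) stacked in 4H."""

    def __init__(self, in_features: int, units: int):
        self.in_features = in_features
        self.units = units
        self.Wx = np.zeros((in_features, 4 * units))
        self.Wh = np.zeros((units, 4 * units))
        self.b = np.zeros(4 * units)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def init(self, rng):
        H = self.units
        self.Wx = glorot_uniform(rng, self.Wx.shape, self.in_features, 4 * H)
        self.Wh = glorot_uniform(rng, self.Wh.shape, H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # forget-gate bias

    def forward(self, x):
        B, T, D = x.shape
        H = self.units
        self._x = x
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs

    def backward(self, dhs):
        x = self._x
        B, T, D = x.shape
        H = self.units
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            self.dWx += x[:, t].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM returning the full output sequence (B, T, 2H)."""

    def __init__(self, in_features: int, units: int):
        self.units = units
        self.fwd = _LSTMDirection(in_features, units)
        self.bwd = _LSTMDirection(in_features, units)

    def init(self, rng):
        self.fwd.init(rng)
        self.bwd.init(rng)

    def forward(self, x, training=False):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy):
        H = self.units
        dxf = self.fwd.backward(dy[:, :, :H])
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, H:]))[:, ::-1]
        return dxf + dxb

    def params(self):
        return [self.fwd.Wx, self.fwd.Wh, self.fwd.b,
                self.bwd.Wx, self.bwd.Wh, self.bwd.b]

    def grads(self):
        return [self.fwd.dWx, self.fwd.dWh, self.fwd.db,
                self.bwd.dWx, self.bwd.dWh, self.bwd.db]

    def out_shape(self, in_shape):
        T, D = in_shape
        return (T, 2 * self.units)
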