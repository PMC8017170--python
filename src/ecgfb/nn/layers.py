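"""Minimal NumPy neural-network layers with explicit backpropagation.

Conventions
-----------
* Sequence tensors are batch-major: ``(B, L, C)`` for convolutional layers
  and ``(B, T, D)`` for recurrent ones.
* Every layer owns its :class:`Param` objects, caches what it needs during
  ``forward`` and returns ``d(input)`` from ``backward`` while accumulating
  parameter gradients.
* All arithmetic is float32; initialisation is seeded through the
  ``rng`` passed to each constructor, so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_padding(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(pad_left, pad_right, out_length) for 'same'-style conv padding."""
    out_length = -(-length // stride)  # ceil
    pad_total = max((out_length - 1) * stride + kernel - length, 0)
    pad_left = pad_total // 2
    return pad_left, pad_total - pad_left, out_length


class Conv1D(Layer):
    """1-D convolution (cross-correlation) with 'same' padding.

    Weight shape is ``(kernel, in_channels, out_channels)``; the forward
    pass is an im2col matmul, the input gradient a per-tap scatter-add.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.kernel, self.stride = kernel, stride
        self.in_channels, self.out_channels = in_channels, out_channels
        scale = np.sqrt(2.0 / (kernel * in_channels))  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, scale, size=(kernel, in_channels, out_channels)))
        self.b = Param(np.zeros(out_channels))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, L, C = x.shape
        pl, pr, Lout = _same_padding(L, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0))).astype(F32, copy=False)
        # windows: (B, n_windows, C, K) -> (B, Lout, K, C)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        win = win[:, ::self.stride][:, :Lout]
        cols = np.ascontiguousarray(np.swapaxes(win, 2, 3)).reshape(B * Lout, -1)
        y = cols @ self.w.value.reshape(-1, self.out_channels) + self.b.value
        self._cache = (cols, (B, L, Lout, pl, pr))
        return y.reshape(B, Lout, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (B, L, Lout, pl, pr) = self._cache
        dy_flat = dy.reshape(B * Lout, self.out_channels).astype(F32, copy=False)
        self.w.grad += (cols.T @ dy_flat).reshape(self.w.value.shape)
        self.b.grad += dy_flat.sum(axis=0)
        dxp = np.zeros((B, L + pl + pr, self.in_channels), dtype=F32)
        dy3 = dy_flat.reshape(B, Lout, self.out_channels)
        for k in range(self.kernel):
            # gradient w.r.t. the k-th tap of every window
            contrib = dy3 @ self.w.value[k].T  # (B, Lout, Cin)
            dxp[:, k:k + self.stride * Lout:self.stride] += contrib
        return dxp[:, pl:pl + L]


class BatchNorm(Layer):
    """Batch normalisation over batch and length axes, per channel."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat.astype(F32), inv_std.astype(F32), axes,
                       np.prod([x.shape[a] for a in axes]))
        return (self.gamma.value * xhat + self.beta.value).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, n = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        # standard batch-norm gradient through the batch statistics
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) * inv_std
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0).astype(F32)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing partial window is dropped."""

    def __init__(self, pool: int = 3):
        if pool < 1:
            raise ValueError(f"pool size must be >= 1, got {pool}")
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, L, C = x.shape
        Lout = L // self.pool
        xr = x[:, :Lout * self.pool].reshape(B, Lout, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._shape = (B, L, C, Lout)
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C, Lout = self._shape
        dxr = np.zeros((B, Lout, self.pool, C), dtype=F32)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=F32)
        dx[:, :Lout * self.pool] = dxr.reshape(B, Lout * self.pool, C)
        return dx


class GlobalAvgPool(Layer):
    """Collapse the length axis to one value per channel."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (np.repeat(dy[:, None, :], self._length, axis=1) / self._length).astype(F32)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / d_in)
        self.w = Param(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.w.value.T).astype(F32)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=F32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """Unidirectional LSTM returning the full hidden-state sequence.

    Gate order in the fused weight matrices is (input, forget, cell, output);
    the forget-gate bias starts at 1 to ease early training.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d_in, self.units = d_in, units
        sw = np.sqrt(1.0 / d_in)
        su = np.sqrt(1.0 / units)
        self.w = Param(rng.normal(0.0, sw, size=(d_in, 4 * units)))
        self.u = Param(rng.normal(0.0, su, size=(units, 4 * units)))
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0
        self.b = Param(b)

    def params(self) -> list[Param]:
        return [self.w, self.u, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        hs = np.zeros((B, T, H), dtype=F32)
        cache = []
        for t in range(T):
            z = x[:, t] @ self.w.value + h @ self.u.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = (x, hs, cache)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, hs, cache = self._cache
        B, T, _ = x.shape
        H = self.units
        dx = np.zeros_like(x, dtype=F32)
        dh_next = np.zeros((B, H), dtype=F32)
        dc_next = np.zeros((B, H), dtype=F32)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1).astype(F32)
            self.w.grad += x[:, t].T @ dz
            self.u.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.w.value.T
            dh_next = dz @ self.u.value.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Forward and backward LSTM over the sequence; outputs concatenated."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(d_in, units, rng)
        self.bwd = LSTM(d_in, units, rng)
        self.units = units

    def params(self) -> list[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1], train)[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        H = self.units
        dxf = self.fwd.backward(np.ascontiguousarray(dy[:, :, :H]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, H:]))[:, ::-1]
        return (dxf + dxb).astype(F32)


class AdditiveAttention(Layer):
    """Additive (learned-query) attention pooling over a sequence.

    Each step ``h_t`` is scored ``e_t = v . tanh(W h_t + b)``; softmax of
    the scores gives non-negative weights summing to one, and the context
    vector is the weighted sum of the steps.
    """

    def __init__(self, d_in: int, attention_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / d_in)
        self.w = Param(rng.normal(0.0, scale, size=(d_in, attention_dim)))
        self.b = Param(np.zeros(attention_dim))
        self.v = Param(rng.normal(0.0, np.sqrt(1.0 / attention_dim), size=(attention_dim,)))

    def params(self) -> list[Param]:
        return [self.w, self.b, self.v]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        # x: (B, T, D) -> context (B, D); weights cached / retrievable
        u = np.tanh(x @ self.w.value + self.b.value)          # (B, T, A)
        scores = u @ self.v.value                             # (B, T)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        a = e / e.sum(axis=1, keepdims=True)                  # (B, T)
        context = np.einsum("bt,btd->bd", a, x).astype(F32)
        self._cache = (x, u, a)
        return context

    @property
    def last_weights(self) -> np.ndarray:
        return self._cache[2]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, u, a = self._cache
        # context = sum_t a_t x_t
        da = np.einsum("bd,btd->bt", dy, x)
        dx = a[:, :, None] * dy[:, None, :]
        # softmax backward
        dscores = a * (da - (da * a).sum(axis=1, keepdims=True))
        self.v.grad += (u * dscores[:, :, None]).sum(axis=(0, 1))
        du = dscores[:, :, None] * self.v.value
        dpre = du * (1.0 - u * u)
        B, T, _ = x.shape
        self.w.grad += x.reshape(B * T, -1).T @ dpre.reshape(B * T, -1)
        self.b.grad += dpre.sum(axis=(0, 1))
        dx += dpre @ self.w.value.T
        return dx.astype(F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    return _sigmoid(np.asarray(z, dtype=F32))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dlogits)."""
    z = np.asarray(logits, dtype=F32).ravel()
    y = np.asarray(targets, dtype=F32).ravel()
    # log(1 + exp(-|z|)) + max(z, 0) - z*y  is the stable BCE-with-logits form
    loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * y))
    p = _sigmoid(z)
    dz = ((p - y) / z.size).astype(F32)
    return loss, dz.reshape(np.shape(logits))
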