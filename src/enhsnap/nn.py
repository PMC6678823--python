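"""Minimal numpy compute core for the small sequence classifiers.

Implements exactly the layer vocabulary the architecture catalog needs —
dense, 1D convolution (valid padding, stride 1), 1D max pooling, uni- and
bidirectional GRU, dropout — with reverse-mode gradients written out by hand
and an RMSProp update rule.  Models in this package are tiny (order 10^3-10^4
parameters), so plain vectorized numpy is fast enough on one CPU; every
layer's backward pass is verified against central finite differences in the
test suite.

Conventions
-----------
* Sequence activations are ``(N, L, C)``; vector activations are ``(N, C)``.
* All floats are float64 for bitwise-reproducible, checkable gradients.
* Weight matrices use Glorot-uniform initialization, biases start at zero;
  initialization draws come from a caller-supplied ``numpy.random.Generator``
  so a seed fixes the model.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid


class Param:
    """A trainable array with its gradient accumulator and weight penalties."""

    __slots__ = ("name", "value", "grad", "l1", "l2")

    def __init__(self, value: np.ndarray, name: str, l1: float = 0.0, l2: float = 0.0):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name
        self.l1 = l1
        self.l2 = l2

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Forward/backward pair with cached intermediates from the last forward."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_features: int, units: int, rng: np.random.Generator,
                 activation: str | None = "relu", l1: float = 0.0, l2: float = 0.0,
                 name: str = "dense"):
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.W = Param(glorot_uniform(rng, (in_features, units)), f"{name}.W", l1, l2)
        self.b = Param(np.zeros(units), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        z = x @ self.W.value + self.b.value
        self._z = z
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dout):
        if self.activation == "relu":
            dout = dout * (self._z > 0.0)
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Conv1D(Layer):
    """Valid-padding, stride-1 temporal convolution with ReLU."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, l1: float = 0.0, l2: float = 0.0,
                 name: str = "conv1d"):
        self.kernel = kernel
        self.W = Param(glorot_uniform(rng, (kernel * in_channels, filters)),
                       f"{name}.W", l1, l2)
        self.b = Param(np.zeros(filters), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    @staticmethod
    def output_length(L: int, kernel: int) -> int:
        return L - kernel + 1

    def forward(self, x, train=False, rng=None):
        N, L, C = x.shape
        k = self.kernel
        Lout = self.output_length(L, k)
        if Lout < 1:
            raise ValueError(f"sequence length {L} shorter than kernel {k}")
        # (N, Lout, C, k) -> (N, Lout, k, C) -> (N, Lout, k*C)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(N, Lout, k * C)
        self._win, self._shape = win, (N, L, C)
        z = win @ self.W.value + self.b.value
        self._z = z
        return np.maximum(z, 0.0)

    def backward(self, dout):
        N, L, C = self._shape
        k = self.kernel
        Lout = dout.shape[1]
        dz = dout * (self._z > 0.0)
        F = dz.shape[-1]
        self.W.grad += self._win.reshape(-1, k * C).T @ dz.reshape(-1, F)
        self.b.grad += dz.sum(axis=(0, 1))
        dwin = (dz @ self.W.value.T).reshape(N, Lout, k, C)
        dx = np.zeros((N, L, C))
        for j in range(k):
            dx[:, j:j + Lout, :] += dwin[:, :, j, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping temporal max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    @staticmethod
    def output_length(L: int, pool: int) -> int:
        return L // pool

    def forward(self, x, train=False, rng=None):
        N, L, C = x.shape
        p = self.pool
        Lp = L // p
        xr = x[:, :Lp * p].reshape(N, Lp, p, C)
        self._argmax = xr.argmax(axis=2)
        self._shape = (N, L, C)
        return xr.max(axis=2)

    def backward(self, dout):
        N, L, C = self._shape
        p = self.pool
        Lp = L // p
        dxr = np.zeros((N, Lp, p, C))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((N, L, C))
        dx[:, :Lp * p] = dxr.reshape(N, Lp * p, C)
        return dx


class _GRUCell:
    """One direction of a GRU layer (Cho et al. gating).

    Gates per step for input x_t and state h:
        z = sigmoid(x_t Wz + h Uz + bz)          (update)
        r = sigmoid(x_t Wr + h Ur + br)          (reset)
        c = tanh(x_t Wc + (r*h) Uc + bc)         (candidate)
        h' = z*h + (1-z)*c
    Input projections for the whole sequence are batched into one matmul;
    only the recurrent part loops over time.
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 l1: float, l2: float, name: str):
        H = hidden
        self.H = H
        self.W = Param(glorot_uniform(rng, (input_size, 3 * H)), f"{name}.W", l1, l2)
        self.U_zr = Param(glorot_uniform(rng, (H, 2 * H)), f"{name}.U_zr", l1, l2)
        self.U_c = Param(glorot_uniform(rng, (H, H)), f"{name}.U_c", l1, l2)
        self.b = Param(np.zeros(3 * H), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.W, self.U_zr, self.U_c, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Run over (N, L, C); returns the full hidden sequence (N, L, H)."""
        N, L, C = x.shape
        H = self.H
        Xp = (x.reshape(N * L, C) @ self.W.value + self.b.value).reshape(N, L, 3 * H)
        h = np.zeros((N, H))
        hs = np.empty((N, L, H))
        cache = []
        for t in range(L):
            azr = Xp[:, t, :2 * H] + h @ self.U_zr.value
            z = sigmoid(azr[:, :H])
            r = sigmoid(azr[:, H:])
            rh = r * h
            c = np.tanh(Xp[:, t, 2 * H:] + rh @ self.U_c.value)
            h_new = z * h + (1.0 - z) * c
            cache.append((h, z, r, rh, c))
            hs[:, t] = h_new
            h = h_new
        self._x, self._cache = x, cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        """Backprop through time; ``dhs`` is (N, L, H) upstream gradient."""
        x, cache = self._x, self._cache
        N, L, C = x.shape
        H = self.H
        dXp = np.empty((N, L, 3 * H))
        dh = np.zeros((N, H))
        Uc_T = self.U_c.value.T
        Uzr_T = self.U_zr.value.T
        dU_zr = np.zeros_like(self.U_zr.value)
        dU_c = np.zeros_like(self.U_c.value)
        for t in range(L - 1, -1, -1):
            dh = dh + dhs[:, t]
            h_prev, z, r, rh, c = cache[t]
            dz = dh * (h_prev - c)
            dc = dh * (1.0 - z)
            dh_prev = dh * z
            dac = dc * (1.0 - c * c)
            drh = dac @ Uc_T
            dU_c += rh.T @ dac
            dr = drh * h_prev
            dh_prev += drh * r
            dazr = np.concatenate([dz * z * (1.0 - z), dr * r * (1.0 - r)], axis=1)
            dU_zr += h_prev.T @ dazr
            dh_prev += dazr @ Uzr_T
            dXp[:, t, :2 * H] = dazr
            dXp[:, t, 2 * H:] = dac
            dh = dh_prev
        self.U_zr.grad += dU_zr
        self.U_c.grad += dU_c
        flat = dXp.reshape(N * L, 3 * H)
        self.W.grad += x.reshape(N * L, C).T @ flat
        self.b.grad += flat.sum(axis=0)
        return (flat @ self.W.value.T).reshape(N, L, C)


class GRU(Layer):
    """GRU layer, optionally bidirectional (direction outputs concatenated).

    ``return_sequences`` controls whether the full hidden sequence or only the
    final state feeds the next layer (final forward state, and for the reverse
    direction the state after reading the whole sequence backwards).
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 bidirectional: bool = False, return_sequences: bool = False,
                 l1: float = 0.0, l2: float = 0.0, name: str = "gru"):
        self.hidden = hidden
        self.bidirectional = bidirectional
        self.return_sequences = return_sequences
        self.fwd = _GRUCell(input_size, hidden, rng, l1, l2, f"{name}.fwd")
        self.bwd = (_GRUCell(input_size, hidden, rng, l1, l2, f"{name}.bwd")
                    if bidirectional else None)

    @property
    def output_size(self) -> int:
        return self.hidden * (2 if self.bidirectional else 1)

    def params(self) -> list[Param]:
        ps = self.fwd.params()
        if self.bwd is not None:
            ps = ps + self.bwd.params()
        return ps

    def forward(self, x, train=False, rng=None):
        hs_f = self.fwd.forward(x)
        if self.bwd is None:
            return hs_f if self.return_sequences else hs_f[:, -1]
        hs_b_rev = self.bwd.forward(x[:, ::-1])
        if self.return_sequences:
            return np.concatenate([hs_f, hs_b_rev[:, ::-1]], axis=2)
        return np.concatenate([hs_f[:, -1], hs_b_rev[:, -1]], axis=1)

    def backward(self, dout):
        H = self.hidden
        N, L, _ = self.fwd._x.shape
        if self.return_sequences:
            df = dout[:, :, :H]
        else:
            df = np.zeros((N, L, H))
            df[:, -1] = dout[:, :H]
        dx = self.fwd.backward(df)
        if self.bwd is not None:
            if self.return_sequences:
                db = dout[:, :, H:][:, ::-1]
            else:
                db = np.zeros((N, L, H))
                db[:, -1] = dout[:, H:]
            dx = dx + self.bwd.backward(db)[:, ::-1]
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("train-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    dlogits = (sigmoid(logits) - y) / n
    return loss, dlogits


def regularization_loss(params: list[Param]) -> float:
    total = 0.0
    for p in params:
        if p.l1:
            total += p.l1 * np.abs(p.value).sum()
        if p.l2:
            total += p.l2 * np.square(p.value).sum()
    return total


class RMSProp:
    """RMSProp with the common defaults (decay 0.9, epsilon 1e-7).

    Weight penalties (L1/L2) attached to a ``Param`` are folded into its
    gradient at step time.
    """

    def __init__(self, params: list[Param], rho: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.rho = rho
        self.eps = eps
        self.acc = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        for p, a in zip(self.params, self.acc):
            g = p.grad
            if p.l1 or p.l2:
                g = g + p.l1 * np.sign(p.value) + 2.0 * p.l2 * p.value
            a *= self.rho
            a += (1.0 - self.rho) * g * g
            p.value -= lr * g / (np.sqrt(a) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
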