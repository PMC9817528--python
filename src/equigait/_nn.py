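"""Minimal numpy neural-network core for the sequence classifiers.

Implements exactly what the gait models need — dense layers, LSTM/GRU
recurrences with backprop-through-time, dilated 1-D convolution, softmax
cross-entropy and Adam — in float32 with explicit, hand-derived gradients.
Every source of randomness goes through a caller-supplied Generator, so a
fixed seed gives bitwise-identical weights.

Array conventions: batches of sequences are ``(B, T, F)`` for recurrent
layers and ``(B, C, T)`` for convolutions.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameters and gradients are parallel dicts of arrays."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Dense(Layer):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int) -> None:
        super().__init__()
        self.params["W"] = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class LSTMCellSeq(Layer):
    """Single-layer LSTM over a full sequence; returns all hidden states.

    Gate order in the fused weight matrices is (i, f, g, o); the forget-gate
    bias is initialised to 1.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int) -> None:
        super().__init__()
        H = n_hidden
        self.H = H
        self.params["Wx"] = _glorot(rng, n_in, 4 * H, (n_in, 4 * H))
        self.params["Wh"] = _glorot(rng, H, 4 * H, (H, 4 * H))
        b = np.zeros(4 * H, dtype=DTYPE)
        b[H : 2 * H] = 1.0
        self.params["b"] = b

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        # pre-compute the input projection for all timesteps at once
        xp = x.reshape(B * T, -1) @ Wx
        xp = xp.reshape(B, T, 4 * H) + b
        hs = np.empty((B, T, H), dtype=DTYPE)
        cache = []
        for t in range(T):
            a = xp[:, t] + h @ Wh
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._x, self._cache = x, cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, cache = self._x, self._cache
        B, T, _ = x.shape
        H = self.H
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx, dWh, db = self.grads["Wx"], self.grads["Wh"], self.grads["b"]
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        da_all = np.empty((B, T, 4 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            da_all[:, t] = da
            dWh += h_prev.T @ da
            dh_next = da @ Wh.T
        flat = da_all.reshape(B * T, 4 * H)
        dWx += x.reshape(B * T, -1).T @ flat
        db += flat.sum(axis=0)
        dx[:] = (flat @ Wx.T).reshape(x.shape)
        return dx


class GRUCellSeq(Layer):
    """Single-layer GRU over a full sequence; returns all hidden states.

    Uses the convention with a separate hidden bias on the candidate term:
    ``n = tanh(x Wxn + bn + r * (h Whn + bhn))``.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int) -> None:
        super().__init__()
        H = n_hidden
        self.H = H
        # fused gate order (r, z, n)
        self.params["Wx"] = _glorot(rng, n_in, 3 * H, (n_in, 3 * H))
        self.params["Wh"] = _glorot(rng, H, 3 * H, (H, 3 * H))
        self.params["b"] = np.zeros(3 * H, dtype=DTYPE)
        self.params["bh"] = np.zeros(H, dtype=DTYPE)  # hidden bias of n-term

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        Wx, Wh, b, bh = (
            self.params["Wx"],
            self.params["Wh"],
            self.params["b"],
            self.params["bh"],
        )
        h = np.zeros((B, H), dtype=DTYPE)
        xp = (x.reshape(B * T, -1) @ Wx).reshape(B, T, 3 * H) + b
        hs = np.empty((B, T, H), dtype=DTYPE)
        cache = []
        for t in range(T):
            hp = h @ Wh
            r = _sigmoid(xp[:, t, :H] + hp[:, :H])
            z = _sigmoid(xp[:, t, H : 2 * H] + hp[:, H : 2 * H])
            m = hp[:, 2 * H :] + bh
            n = np.tanh(xp[:, t, 2 * H :] + r * m)
            h_prev = h
            h = (1.0 - z) * n + z * h_prev
            hs[:, t] = h
            cache.append((r, z, n, m, h_prev))
        self._x, self._cache = x, cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        x, cache = self._x, self._cache
        B, T, _ = x.shape
        H = self.H
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx, dWh, db, dbh = (
            self.grads["Wx"],
            self.grads["Wh"],
            self.grads["b"],
            self.grads["bh"],
        )
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        da_all = np.empty((B, T, 3 * H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            r, z, n, m, h_prev = cache[t]
            dh = dhs[:, t] + dh_next
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            da_n = dn * (1.0 - n * n)  # grad wrt (x Wxn + bn + r m)
            dr = da_n * m
            dm = da_n * r
            da_r = dr * r * (1.0 - r)
            da_z = dz * z * (1.0 - z)
            da = np.concatenate([da_r, da_z, da_n], axis=1)
            da_all[:, t] = da
            # hidden-side pre-activations: (r, z) share Wh columns; n-term is m
            dhp = np.concatenate([da_r, da_z, dm], axis=1)
            dWh += h_prev.T @ dhp
            dbh += dm.sum(axis=0)
            dh_next = dh_prev + dhp @ Wh.T
        flat = da_all.reshape(B * T, 3 * H)
        dWx += x.reshape(B * T, -1).T @ flat
        db += flat.sum(axis=0)
        dx[:] = (flat @ Wx.T).reshape(x.shape)
        return dx


class DilatedConv1d(Layer):
    """Length-preserving 1-D convolution, kernel 3, arbitrary dilation."""

    def __init__(
        self, rng: np.random.Generator, n_in: int, n_out: int, dilation: int
    ) -> None:
        super().__init__()
        self.d = dilation
        self.k = 3
        fan_in = n_in * self.k
        self.params["W"] = _glorot(rng, fan_in, n_out, (n_out, n_in, self.k))
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, T = x.shape
        d = self.d
        xp = np.pad(x, ((0, 0), (0, 0), (d, d)))
        # (B, C, T, k): taps at offsets 0, d, 2d into the padded signal
        taps = np.stack([xp[:, :, j * d : j * d + T] for j in range(self.k)], axis=-1)
        self._taps_shape = (B, C, T)
        self._taps = taps
        y = np.einsum("bctk,ock->bot", taps, self.params["W"], optimize=True)
        return y + self.params["b"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, T = self._taps_shape
        d = self.d
        W = self.params["W"]
        self.grads["W"] += np.einsum("bctk,bot->ock", self._taps, dout, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2))
        dxp = np.zeros((B, C, T + 2 * d), dtype=DTYPE)
        for j in range(self.k):
            dxp[:, :, j * d : j * d + T] += np.einsum(
                "bot,oc->bct", dout, W[:, :, j], optimize=True
            )
        return dxp[:, :, d : d + T]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    B = len(y)
    loss = -np.log(np.clip(p[np.arange(B), y], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return float(loss), (dlogits / B).astype(DTYPE)


class Adam:
    """Adam with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, layers, lr: float = 1e-3) -> None:
        self.layers = list(layers)
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [
            {k: np.zeros_like(p) for k, p in lay.params.items()} for lay in self.layers
        ]
        self.v = [
            {k: np.zeros_like(p) for k, p in lay.params.items()} for lay in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.b1 * m[k] + (1.0 - self.b1) * g
                v[k] = self.b2 * v[k] + (1.0 - self.b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
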