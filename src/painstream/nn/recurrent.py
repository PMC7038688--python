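"""LSTM recurrences with full backpropagation through time.

The cell follows the standard formulation: forget, input and output gates
squashed by the logistic sigmoid, a tanh cell-state candidate, and
h_t = o_t * tanh(C_t).  Gates are packed [i, f, c~, o] into fused weight
matrices so each time step costs two GEMMs.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from painstream.nn.layers import Layer, Param

_F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Unidirectional LSTM over (batch, time, features) returning every
    hidden state, shape (batch, time, units)."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 reverse: bool = False, name: str = "lstm") -> None:
        limit = np.sqrt(6.0 / (d_in + units))
        self.wx = Param(rng.uniform(-limit, limit, (d_in, 4 * units)), f"{name}.wx")
        rlimit = np.sqrt(6.0 / (2 * units))
        self.wh = Param(rng.uniform(-rlimit, rlimit, (units, 4 * units)), f"{name}.wh")
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0  # forget-gate bias starts open
        self.b = Param(b, f"{name}.b")
        self.units = units
        self.d_in = d_in
        self.reverse = reverse

    def params(self) -> List[Param]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 3:
            raise ValueError("LSTM expects (batch, time, features)")
        if x.shape[1] == 0:
            raise ValueError("empty sequence")
        if self.reverse:
            x = x[:, ::-1, :]
        B, L, D = x.shape
        U = self.units
        zx = x.reshape(B * L, D) @ self.wx.value + self.b.value
        zx = zx.reshape(B, L, 4 * U)
        h = np.zeros((B, U), dtype=_F32)
        c = np.zeros((B, U), dtype=_F32)
        gates = np.empty((B, L, 4 * U), dtype=_F32)
        cs = np.empty((B, L, U), dtype=_F32)
        hs = np.empty((B, L, U), dtype=_F32)
        for t in range(L):
            z = zx[:, t, :] + h @ self.wh.value
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[:, t, :U] = i
            gates[:, t, U:2 * U] = f
            gates[:, t, 2 * U:3 * U] = g
            gates[:, t, 3 * U:] = o
            cs[:, t] = c
            hs[:, t] = h
        if train:
            self._cache = (x, gates, cs, hs)
        out = hs[:, ::-1, :] if self.reverse else hs
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, gates, cs, hs = self._cache
        if self.reverse:
            dout = dout[:, ::-1, :]
        B, L, U = hs.shape
        dz_all = np.empty((B, L, 4 * U), dtype=_F32)
        dh_next = np.zeros((B, U), dtype=_F32)
        dc_next = np.zeros((B, U), dtype=_F32)
        whT = self.wh.value.T
        for t in range(L - 1, -1, -1):
            i = gates[:, t, :U]
            f = gates[:, t, U:2 * U]
            g = gates[:, t, 2 * U:3 * U]
            o = gates[:, t, 3 * U:]
            c = cs[:, t]
            tanh_c = np.tanh(c)
            dh = dout[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
            c_prev = cs[:, t - 1] if t > 0 else np.zeros_like(c)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dz_all[:, t, :] = dz
            dh_next = dz @ whT
            dc_next = dc * f
        dz_flat = dz_all.reshape(B * L, 4 * U)
        self.wx.grad = x.reshape(B * L, -1).T @ dz_flat
        self.b.grad = dz_flat.sum(axis=0)
        # recurrent weights see h_{t-1}: shift hidden states right by one
        h_prev = np.zeros_like(hs)
        h_prev[:, 1:, :] = hs[:, :-1, :]
        self.wh.grad = h_prev.reshape(B * L, U).T @ dz_flat
        dx = (dz_flat @ self.wx.value.T).reshape(B, L, -1)
        self._cache = None
        if self.reverse:
            dx = dx[:, ::-1, :]
        return np.ascontiguousarray(dx)


class BiLSTM(Layer):
    """Forward and backward LSTMs over the same input; hidden states are
    concatenated per time step, giving (batch, time, 2*units)."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 name: str = "bilstm") -> None:
        self.fwd = LSTM(d_in, units, rng, reverse=False, name=f"{name}.fwd")
        self.bwd = LSTM(d_in, units, rng, reverse=True, name=f"{name}.bwd")
        self.units = units

    def params(self) -> List[Param]:
        return self.fwd.params() + self.bwd.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        hf = self.fwd.forward(x, train=train)
        hb = self.bwd.forward(x, train=train)
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        U = self.units
        dxf = self.fwd.backward(np.ascontiguousarray(dout[:, :, :U]))
        dxb = self.bwd.backward(np.ascontiguousarray(dout[:, :, U:]))
        return dxf + dxb
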