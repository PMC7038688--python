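"""Frame-attention pooling.

Each time step's BiLSTM output h_k is scored by a single learned linear
functional passed through an elu, the scores are softmax-normalised over
the sequence into weights a_k (non-negative, summing to one), and the
pooled representation is the convex combination sum_k a_k * h_k.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from painstream.nn.layers import Layer, Param, elu, softmax

_F32 = np.float32


class AttentionPool(Layer):
    """(batch, time, dim) -> (batch, dim); stores the last attention
    weights in ``last_weights`` (batch, time)."""

    def __init__(self, d_in: int, rng: np.random.Generator,
                 alpha: float = 1.0, name: str = "attn") -> None:
        limit = np.sqrt(6.0 / (d_in + 1))
        self.w = Param(rng.uniform(-limit, limit, size=d_in), f"{name}.w")
        self.b = Param(np.zeros(1), f"{name}.b")
        self.alpha = alpha
        self.last_weights: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, h: np.ndarray, train: bool = False) -> np.ndarray:
        if h.ndim != 3 or h.shape[1] < 1:
            raise ValueError("attention expects a non-empty (batch, time, dim) input")
        score = elu(h @ self.w.value + self.b.value[0], self.alpha)  # (B, L)
        a = softmax(score, axis=1).astype(_F32)
        pooled = np.einsum("bl,bld->bd", a, h, optimize=True).astype(_F32)
        self.last_weights = a
        if train:
            self._cache = (h, score.astype(_F32), a)
        return pooled

    def backward(self, dpooled: np.ndarray) -> np.ndarray:
        h, score, a = self._cache  # score is the post-elu activation
        da = np.einsum("bd,bld->bl", dpooled, h, optimize=True)
        dh = a[:, :, None] * dpooled[:, None, :]
        # softmax over the time axis
        dscore = a * (da - np.sum(a * da, axis=1, keepdims=True))
        # elu'(x) = 1 for x >= 0 else elu(x) + alpha, recovered from the output
        dz = dscore * np.where(score >= 0, 1.0, score + self.alpha)
        self.w.grad = np.einsum("bl,bld->d", dz, h, optimize=True)
        self.b.grad = np.array([dz.sum()], dtype=_F32)
        dh += dz[:, :, None] * self.w.value[None, None, :]
        self._cache = None
        return dh.astype(_F32, copy=False)
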