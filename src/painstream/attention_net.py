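"""One stream of the two-stream classifier: a time-distributed VGG-style
convolutional embedder, a bidirectional LSTM, frame-attention pooling and
a small MLP classifier.

The embedder applies the same 10-layer CNN (four blocks of 3x3
convolutions with elu activations, each block closed by 2x2 max pooling
and batch normalisation) to every frame of the input stack, producing one
flattened feature vector per frame.  A BiLSTM (64 units per direction)
integrates the temporal axis, the attention layer collapses the sequence
into a single convex combination of hidden states, and a
dropout/dense/dropout/dense head yields class probabilities.

This module also exposes plain-NumPy reference operations —
:func:`lstm_cell_step` and :func:`attention_pool` — that spell out the
recurrences the batched layers implement, for use as independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from painstream.nn import (
    AttentionPool, BatchNorm, BiLSTM, Conv2D, Dense, Dropout, Elu, Flatten,
    MaxPool2D, Param, Sequential, softmax,
)
from painstream.nn.layers import Layer, elu

_F32 = np.float32

__all__ = [
    "EmbedderConfig", "NetConfig", "LSTMCellParams", "AttentionOutput",
    "AttentionNetwork", "build_embedder", "lstm_cell_step", "attention_pool",
    "embedded_feature_dim",
]


@dataclass(frozen=True)
class EmbedderConfig:
    """Convolutional embedder layout: (layer_count, filter_count) per
    block; 3x3 kernels, stride 1, elu activations; every block ends with
    2x2/2x2 max pooling followed by batch normalisation."""

    conv_blocks: Tuple[Tuple[int, int], ...] = ((2, 8), (2, 16), (3, 32), (3, 64))

    def __post_init__(self) -> None:
        filters = [f for _, f in self.conv_blocks]
        if any(b <= a for a, b in zip(filters, filters[1:])) and filters != sorted(filters):
            raise ValueError("filter counts must be non-decreasing")

    @property
    def n_conv_layers(self) -> int:
        return sum(n for n, _ in self.conv_blocks)


@dataclass(frozen=True)
class NetConfig:
    """Full single-stream configuration."""

    embedder: EmbedderConfig = EmbedderConfig()
    lstm_units: int = 64
    classifier_hidden: int = 64
    dropout_rate: float = 0.25
    n_classes: int = 2


@dataclass
class LSTMCellParams:
    """Unfused LSTM cell weights: per-gate input matrices W_*, recurrent
    matrices U_* and biases b_* (gates: input i, forget f, output o, cell
    candidate c)."""

    W_i: np.ndarray; W_f: np.ndarray; W_o: np.ndarray; W_c: np.ndarray
    U_i: np.ndarray; U_f: np.ndarray; U_o: np.ndarray; U_c: np.ndarray
    b_i: np.ndarray; b_f: np.ndarray; b_o: np.ndarray; b_c: np.ndarray

    @property
    def units(self) -> int:
        return self.U_i.shape[0]

    @classmethod
    def from_fused(cls, wx: np.ndarray, wh: np.ndarray, b: np.ndarray
                   ) -> "LSTMCellParams":
        """Split fused [i, f, c, o] matrices (as used by the batched LSTM
        layer) into per-gate blocks."""
        u = wh.shape[0]
        i, f, c, o = (slice(0, u), slice(u, 2 * u), slice(2 * u, 3 * u),
                      slice(3 * u, 4 * u))
        return cls(
            W_i=wx[:, i].T, W_f=wx[:, f].T, W_o=wx[:, o].T, W_c=wx[:, c].T,
            U_i=wh[:, i].T, U_f=wh[:, f].T, U_o=wh[:, o].T, U_c=wh[:, c].T,
            b_i=b[i], b_f=b[f], b_o=b[o], b_c=b[c],
        )


def _sigma(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
    p: LSTMCellParams,
) -> Tuple[np.ndarray, np.ndarray]:
    """Reference LSTM cell update for a single time step.

    f_t = sigma(W_f x + U_f h + b_f);  i_t = sigma(W_i x + U_i h + b_i);
    c~_t = tanh(W_c x + U_c h + b_c);  C_t = f_t*C_{t-1} + i_t*c~_t;
    o_t = sigma(W_o x + U_o h + b_o);  h_t = o_t * tanh(C_t).
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    f = _sigma(p.W_f @ x_t + p.U_f @ h_prev + p.b_f)
    i = _sigma(p.W_i @ x_t + p.U_i @ h_prev + p.b_i)
    c_tilde = np.tanh(p.W_c @ x_t + p.U_c @ h_prev + p.b_c)
    c_t = f * c_prev + i * c_tilde
    o = _sigma(p.W_o @ x_t + p.U_o @ h_prev + p.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


@dataclass
class AttentionOutput:
    """Softmax-normalised frame weights and the pooled representation."""

    weights: np.ndarray
    pooled: np.ndarray


def attention_pool(h: np.ndarray, w: np.ndarray, b: float,
                   alpha: float = 1.0) -> AttentionOutput:
    """Reference attention pooling of a single sequence (l, d):
    scores alpha_k = elu(w . h_k + b), weights a = softmax(alpha),
    pooled = sum_k a_k h_k."""
    h = np.asarray(h, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("expected a non-empty (time, dim) array")
    scores = elu(h @ np.asarray(w, dtype=np.float64) + b, alpha)
    a = softmax(scores)
    pooled = a @ h
    return AttentionOutput(weights=a, pooled=pooled)


def build_embedder(cfg: EmbedderConfig, in_channels: int,
                   rng: np.random.Generator) -> Sequential:
    """Assemble the per-frame CNN: conv(elu) x n, maxpool, batchnorm per
    block, then flatten."""
    layers: List[Layer] = []
    c_in = in_channels
    first = True
    for bi, (n_layers, filters) in enumerate(cfg.conv_blocks):
        for li in range(n_layers):
            layers.append(Conv2D(c_in, filters, rng, skip_input_grad=first,
                                 name=f"b{bi}c{li}"))
            layers.append(Elu())
            c_in = filters
            first = False
        layers.append(MaxPool2D())
        layers.append(BatchNorm(filters, name=f"b{bi}.bn"))
    layers.append(Flatten())
    return Sequential(layers)


def embedded_feature_dim(cfg: EmbedderConfig, height: int, width: int) -> int:
    """Flattened feature length for a given input size (each block halves
    the spatial dimensions by floor division)."""
    h, w = height, width
    for _ in cfg.conv_blocks:
        h, w = h // 2, w // 2
    if h < 1 or w < 1:
        raise ValueError("input too small for four 2x2 poolings")
    return h * w * cfg.conv_blocks[-1][1]


class AttentionNetwork:
    """A full single-stream model operating on (batch, time, h, w, c)
    stacks of motion-representation images."""

    def __init__(self, cfg: NetConfig, in_shape: Tuple[int, int, int],
                 seed: int = 0) -> None:
        h, w, c = in_shape
        if h // 16 < 1 or w // 16 < 1:
            raise ValueError("frames must be at least 16x16 for four poolings")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.in_shape = in_shape
        self.embedder = build_embedder(cfg.embedder, c, rng)
        feat = embedded_feature_dim(cfg.embedder, h, w)
        self.bilstm = BiLSTM(feat, cfg.lstm_units, rng)
        self.attention = AttentionPool(2 * cfg.lstm_units, rng)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0])
        self.classifier = Sequential([
            Dropout(cfg.dropout_rate, self._dropout_rng),
            Dense(2 * cfg.lstm_units, cfg.classifier_hidden, rng, name="fc1"),
            Elu(),
            Dropout(cfg.dropout_rate, self._dropout_rng),
            Dense(cfg.classifier_hidden, cfg.n_classes, rng, name="fc2"),
        ])
        self.feature_dim = feat

    def params(self) -> List[Param]:
        return (self.embedder.params() + self.bilstm.params()
                + self.attention.params() + self.classifier.params())

    def embed_frames(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(batch, time, h, w, c) -> (batch, time, feature_dim), the same
        embedder weights applied to every frame."""
        B, L = x.shape[:2]
        flat = np.ascontiguousarray(x, dtype=_F32).reshape((B * L,) + x.shape[2:])
        feats = self.embedder.forward(flat, train=train)
        self._bl = (B, L)
        return feats.reshape(B, L, -1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Full stream forward pass; returns class logits (batch, c)."""
        feats = self.embed_frames(x, train=train)
        hs = self.bilstm.forward(feats, train=train)
        pooled = self.attention.forward(hs, train=train)
        return self.classifier.forward(pooled, train=train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False), axis=1)

    @property
    def last_attention(self) -> Optional[np.ndarray]:
        """Attention weights (batch, time) from the most recent forward."""
        return self.attention.last_weights

    def backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.classifier.backward(dlogits)
        dhs = self.attention.backward(dpooled)
        dfeats = self.bilstm.backward(dhs)
        B, L = self._bl
        self.embedder.backward(
            np.ascontiguousarray(dfeats).reshape(B * L, -1))
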