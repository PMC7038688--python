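"""Two-stream model assembly, constrained score fusion and training.

The two attention streams (optical-flow stream and motion-history stream)
are independent networks.  Their class-probability outputs are combined by
a learned convex combination score = alpha_ofi * score_ofi + alpha_mhi *
score_mhi with alpha_ofi + alpha_mhi = 1.  The constraint is enforced by
construction: the two fusion coefficients are the softmax of two free
scalars, so it holds at initialisation and after every optimiser step.

Training minimises the joint loss
L = lambda_ofi * CE_ofi + lambda_mhi * CE_mhi + lambda_agg * CE_agg,
each term a categorical cross-entropy against the same labels, end-to-end
with Adam for a fixed number of epochs (no early stopping or model
selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from painstream.attention_net import AttentionNetwork, NetConfig
from painstream.nn import Adam, Param, softmax

_F32 = np.float32
_EPS = 1e-7  # floor inside log; guards exact zeros at the true class

__all__ = [
    "FusionWeights", "LossConfig", "TrainConfig", "TwoStreamModel",
    "FusedPrediction", "aggregate_scores", "combined_loss",
    "build_two_stream_model", "train", "predict", "cross_entropy",
]


@dataclass(frozen=True)
class FusionWeights:
    alpha_ofi: float
    alpha_mhi: float

    def __post_init__(self) -> None:
        if self.alpha_ofi < 0 or self.alpha_mhi < 0:
            raise ValueError("fusion weights must be non-negative")
        if abs(self.alpha_ofi + self.alpha_mhi - 1.0) > 1e-6:
            raise ValueError("fusion weights must sum to 1")


@dataclass(frozen=True)
class LossConfig:
    lambda_ofi: float = 0.2
    lambda_mhi: float = 0.2
    lambda_agg: float = 0.6

    def __post_init__(self) -> None:
        if min(self.lambda_ofi, self.lambda_mhi, self.lambda_agg) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    epochs: int = 20
    batch_size: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Batch-mean categorical cross-entropy -sum_j y_j log(y^_j)."""
    probs = np.atleast_2d(probs)
    onehot = np.atleast_2d(onehot)
    return float(-np.mean(np.sum(onehot * np.log(probs + _EPS), axis=1)))


def aggregate_scores(score_ofi: np.ndarray, score_mhi: np.ndarray,
                     w: FusionWeights) -> np.ndarray:
    """Convex combination of two per-class probability vectors (or
    batches thereof)."""
    score_ofi = np.asarray(score_ofi, dtype=np.float64)
    score_mhi = np.asarray(score_mhi, dtype=np.float64)
    if score_ofi.shape != score_mhi.shape:
        raise ValueError("stream scores must share a shape")
    for s in (score_ofi, score_mhi):
        if np.any(s < -1e-9) or np.any(np.abs(s.sum(axis=-1) - 1.0) > 1e-5):
            raise ValueError("stream scores must be probability vectors")
    return w.alpha_ofi * score_ofi + w.alpha_mhi * score_mhi


def combined_loss(preds_ofi: np.ndarray, preds_mhi: np.ndarray,
                  preds_agg: np.ndarray, labels_onehot: np.ndarray,
                  cfg: LossConfig = LossConfig()) -> float:
    """Joint loss: weighted sum of the three cross-entropies."""
    return (cfg.lambda_ofi * cross_entropy(preds_ofi, labels_onehot)
            + cfg.lambda_mhi * cross_entropy(preds_mhi, labels_onehot)
            + cfg.lambda_agg * cross_entropy(preds_agg, labels_onehot))


@dataclass
class FusedPrediction:
    fused: np.ndarray          # (batch, c)
    ofi: np.ndarray            # (batch, c)
    mhi: np.ndarray            # (batch, c)
    attention_ofi: np.ndarray  # (batch, l)
    attention_mhi: np.ndarray  # (batch, l)


class TwoStreamModel:
    """Two independent attention streams plus a trainable constrained
    aggregation layer."""

    def __init__(self, net_cfg: NetConfig, loss_cfg: LossConfig,
                 seq_len: int, frame_hw: Tuple[int, int], seed: int = 0) -> None:
        h, w = frame_hw
        self.net_cfg = net_cfg
        self.loss_cfg = loss_cfg
        self.seq_len = seq_len
        self.frame_hw = frame_hw
        ss = np.random.SeedSequence(seed)
        ofi_seed, mhi_seed = (int(s.generate_state(1)[0] % (2**31))
                              for s in ss.spawn(2))
        self.ofi_net = AttentionNetwork(net_cfg, (h, w, 3), seed=ofi_seed)
        self.mhi_net = AttentionNetwork(net_cfg, (h, w, 1), seed=mhi_seed)
        # softmax of two free scalars keeps the weights on the simplex
        self.fusion_logits = Param(np.zeros(2), "fusion.logits")

    @property
    def fusion_weights(self) -> FusionWeights:
        a = softmax(self.fusion_logits.value)
        return FusionWeights(alpha_ofi=float(a[0]), alpha_mhi=float(a[1]))

    def params(self) -> List[Param]:
        return self.ofi_net.params() + self.mhi_net.params() + [self.fusion_logits]

    def _check_shapes(self, ofi: np.ndarray, mhi: np.ndarray) -> None:
        h, w = self.frame_hw
        if ofi.shape[1:] != (self.seq_len, h, w, 3):
            raise ValueError(f"OFI input must be (b, {self.seq_len}, {h}, {w}, 3); "
                             f"got {ofi.shape}")
        if mhi.shape[1:] != (self.seq_len, h, w, 1):
            raise ValueError(f"MHI input must be (b, {self.seq_len}, {h}, {w}, 1); "
                             f"got {mhi.shape}")
        if ofi.shape[0] != mhi.shape[0]:
            raise ValueError("stream batches must align")

    def forward(self, ofi: np.ndarray, mhi: np.ndarray, train: bool = False
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (p_ofi, p_mhi, p_fused) probability batches."""
        self._check_shapes(ofi, mhi)
        z_ofi = self.ofi_net.forward(ofi, train=train)
        z_mhi = self.mhi_net.forward(mhi, train=train)
        p_ofi = softmax(z_ofi, axis=1)
        p_mhi = softmax(z_mhi, axis=1)
        a = softmax(self.fusion_logits.value)
        p_fused = a[0] * p_ofi + a[1] * p_mhi
        return p_ofi, p_mhi, p_fused

    def train_step_grads(self, ofi: np.ndarray, mhi: np.ndarray,
                         onehot: np.ndarray) -> Dict[str, float]:
        """Forward in training mode, populate all parameter gradients for
        the joint loss, and return the loss terms."""
        cfg = self.loss_cfg
        B = ofi.shape[0]
        p_ofi, p_mhi, p_fused = self.forward(ofi, mhi, train=True)
        a = softmax(self.fusion_logits.value)

        losses = {
            "loss_ofi": cross_entropy(p_ofi, onehot),
            "loss_mhi": cross_entropy(p_mhi, onehot),
            "loss_agg": cross_entropy(p_fused, onehot),
        }
        losses["loss"] = (cfg.lambda_ofi * losses["loss_ofi"]
                          + cfg.lambda_mhi * losses["loss_mhi"]
                          + cfg.lambda_agg * losses["loss_agg"])

        # dL/dp_fused for the aggregation CE (batch-mean)
        dp_f = -cfg.lambda_agg * onehot / (p_fused + _EPS) / B

        # per-stream logits: own CE (exact softmax-CE gradient) + the
        # fused CE routed through the convex combination and the softmax
        def dz_stream(p: np.ndarray, lam: float, alpha: float) -> np.ndarray:
            dp = alpha * dp_f
            dz_fused = p * (dp - np.sum(dp * p, axis=1, keepdims=True))
            dz_own = lam * (p - onehot) / B
            return (dz_own + dz_fused).astype(_F32)

        self.ofi_net.backward(dz_stream(p_ofi, cfg.lambda_ofi, float(a[0])))
        self.mhi_net.backward(dz_stream(p_mhi, cfg.lambda_mhi, float(a[1])))

        da = np.array([np.sum(dp_f * p_ofi), np.sum(dp_f * p_mhi)])
        self.fusion_logits.grad = (a * (da - np.sum(da * a))).astype(_F32)
        return losses


def build_two_stream_model(net_cfg: NetConfig, loss_cfg: LossConfig,
                           seq_len: int, frame_hw: Tuple[int, int],
                           seed: int = 0) -> TwoStreamModel:
    return TwoStreamModel(net_cfg, loss_cfg, seq_len, frame_hw, seed=seed)


def _to_onehot(labels: np.ndarray, c: int) -> np.ndarray:
    onehot = np.zeros((len(labels), c), dtype=_F32)
    onehot[np.arange(len(labels)), labels] = 1.0
    return onehot


def train(model: TwoStreamModel, ofi: np.ndarray, mhi: np.ndarray,
          labels: np.ndarray, cfg: TrainConfig,
          on_step: Optional[Callable[[TwoStreamModel], None]] = None
          ) -> Dict[str, List[float]]:
    """End-to-end training for exactly ``cfg.epochs`` epochs.

    Returns a history with the per-epoch means of all three loss terms,
    the joint loss and the fusion weights.  ``on_step`` (if given) is
    called after every optimiser update.
    """
    if len(labels) == 0:
        raise ValueError("empty training set")
    labels = np.asarray(labels)
    onehot = _to_onehot(labels, model.net_cfg.n_classes)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(labels)
    history: Dict[str, List[float]] = {
        k: [] for k in ("loss", "loss_ofi", "loss_mhi", "loss_agg",
                        "alpha_ofi", "alpha_mhi")}
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        sums = {"loss": 0.0, "loss_ofi": 0.0, "loss_mhi": 0.0, "loss_agg": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            losses = model.train_step_grads(ofi[idx], mhi[idx], onehot[idx])
            opt.step()
            opt.zero_grad()
            if on_step is not None:
                on_step(model)
            for k in sums:
                sums[k] += losses[k]
            n_batches += 1
        for k in sums:
            history[k].append(sums[k] / n_batches)
        w = model.fusion_weights
        history["alpha_ofi"].append(w.alpha_ofi)
        history["alpha_mhi"].append(w.alpha_mhi)
    return history


def predict(model: TwoStreamModel, ofi: np.ndarray, mhi: np.ndarray
            ) -> FusedPrediction:
    """Inference: fused and per-stream probabilities plus the per-frame
    attention weights of both streams."""
    p_ofi, p_mhi, p_fused = model.forward(ofi, mhi, train=False)
    return FusedPrediction(
        fused=p_fused, ofi=p_ofi, mhi=p_mhi,
        attention_ofi=model.ofi_net.last_attention.copy(),
        attention_mhi=model.mhi_net.last_attention.copy(),
    )
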