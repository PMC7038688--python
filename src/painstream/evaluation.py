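"""Leave-one-subject-out evaluation, classification metrics, paired
significance testing and attention-weight profiling.

Metrics follow the macro-averaged convention: per-class precision and
recall are averaged over classes, and the macro F1 is the harmonic mean
of those two macro averages (not the average of per-class F1 scores —
the two differ for asymmetric confusion matrices).  A class with an empty
denominator contributes 0 to its macro average, with a warning; subjects
whose expressions do not differentiate the classes genuinely produce
near-zero scores, so this case is real rather than pathological.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from painstream.fusion import (
    LossConfig, TrainConfig, TwoStreamModel, build_two_stream_model, predict,
    train,
)
from painstream.attention_net import NetConfig
from painstream.pipeline import TwoStreamTensors

__all__ = [
    "ConfusionMatrix", "LOSOResult", "confusion_matrix", "accuracy",
    "macro_metrics", "wilcoxon_compare", "loso_split",
    "attention_weight_profile", "summarise_attention", "run_loso",
]


@dataclass
class ConfusionMatrix:
    """c x c counts; rows are true classes, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def tp(self, i: int) -> int:
        return int(self.counts[i, i])

    def fp(self, i: int) -> int:
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, i: int) -> int:
        return int(self.counts[i, :].sum() - self.counts[i, i])


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int],
                     n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must align")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples, trace / total."""
    if cm.total == 0:
        raise ValueError("accuracy is undefined for an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def macro_metrics(cm: ConfusionMatrix) -> Tuple[float, float, float]:
    """(macro precision, macro recall, macro F1).

    Macro F1 is the harmonic mean of the two macro averages.  Classes
    with zero predicted (precision) or zero true (recall) samples
    contribute 0 and trigger a warning.
    """
    c = cm.n_classes
    if c < 2:
        raise ValueError("macro metrics need at least 2 classes")
    precisions, recalls = [], []
    for i in range(c):
        tp, fp, fn = cm.tp(i), cm.fp(i), cm.fn(i)
        if tp + fp == 0:
            warnings.warn(f"class {i}: no predicted samples; precision set to 0")
            precisions.append(0.0)
        else:
            precisions.append(tp / (tp + fp))
        if tp + fn == 0:
            warnings.warn(f"class {i}: no true samples; recall set to 0")
            recalls.append(0.0)
        else:
            recalls.append(tp / (tp + fn))
    macro_p = float(np.mean(precisions))
    macro_r = float(np.mean(recalls))
    if macro_p + macro_r == 0:
        macro_f1 = 0.0
    else:
        macro_f1 = 2.0 * macro_p * macro_r / (macro_p + macro_r)
    return macro_p, macro_r, macro_f1


def wilcoxon_compare(metric_a: Sequence[float], metric_b: Sequence[float],
                     alpha: float = 0.05) -> Tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired per-subject metrics.

    Zero differences are dropped (the classic convention); the exact null
    distribution is used for fewer than 25 non-zero pairs, the normal
    approximation otherwise.  Returns (statistic, p-value, significant).
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples of equal length required")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    n_nonzero = int(np.sum(diffs != 0))
    if n_nonzero == 0:
        raise ValueError("all paired differences are zero; test undefined")
    method = "exact" if n_nonzero < 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def loso_split(subjects: Sequence) -> List[Tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds: for every subject (sorted order), the
    indices of its trials form the test set and all others the training
    set."""
    subjects = np.asarray(subjects)
    unique = np.unique(subjects)
    if len(unique) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    folds = []
    for s in unique:
        test = np.flatnonzero(subjects == s)
        train_idx = np.flatnonzero(subjects != s)
        folds.append((str(s), train_idx, test))
    return folds


def attention_weight_profile(weights: np.ndarray) -> pd.DataFrame:
    """Per-position summary of attention weights pooled over sequences.

    ``weights`` is (n_sequences, l).  Returns a frame with mean, median,
    lower/upper quartiles per position and the mean curve min-max
    normalised to [0, 1].
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=np.float64))
    mean = weights.mean(axis=0)
    lo, med, hi = np.percentile(weights, [25, 50, 75], axis=0)
    span = mean.max() - mean.min()
    norm = (mean - mean.min()) / span if span > 0 else np.zeros_like(mean)
    return pd.DataFrame({
        "position": np.arange(weights.shape[1]),
        "mean": mean, "median": med, "q25": lo, "q75": hi,
        "normalised_mean": norm,
    })


def summarise_attention(profile: pd.DataFrame) -> Dict[str, float]:
    """First- vs last-quartile mean attention — the skewness summary."""
    l = len(profile)
    q = max(l // 4, 1)
    return {
        "first_quartile_mean": float(profile["mean"].values[:q].mean()),
        "last_quartile_mean": float(profile["mean"].values[-q:].mean()),
    }


@dataclass
class FoldResult:
    subject_id: str
    cm: ConfusionMatrix
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy_ofi: float
    accuracy_mhi: float
    attention_ofi: np.ndarray  # (n_test, l)
    attention_mhi: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    history: Dict[str, List[float]]


@dataclass
class LOSOResult:
    per_subject: Dict[str, FoldResult]
    summary: Dict[str, Tuple[float, float]]  # metric -> (mean, sd)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, r in self.per_subject.items():
            rows.append({
                "subject_id": s, "accuracy": r.accuracy,
                "macro_precision": r.macro_precision,
                "macro_recall": r.macro_recall, "macro_f1": r.macro_f1,
                "accuracy_ofi": r.accuracy_ofi, "accuracy_mhi": r.accuracy_mhi,
            })
        return pd.DataFrame(rows)

    def pooled_attention(self, stream: str) -> np.ndarray:
        key = f"attention_{stream}"
        return np.concatenate([getattr(r, key) for r in self.per_subject.values()])


def _summarise(df: pd.DataFrame) -> Dict[str, Tuple[float, float]]:
    out = {}
    for col in df.columns:
        if col == "subject_id":
            continue
        out[col] = (float(df[col].mean()), float(df[col].std(ddof=1)))
    return out


def run_loso(
    data: TwoStreamTensors,
    net_cfg: NetConfig,
    loss_cfg: LossConfig = LossConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    progress: Optional[Callable[[str], None]] = None,
) -> LOSOResult:
    """Full LOSO cross-validation: one model trained from scratch per
    held-out subject, evaluated on that subject's trials.

    Per fold the fused prediction drives the headline metrics; the
    per-stream heads provide single-stream accuracies and both streams'
    attention-weight matrices are kept (test sequences only).  The driver
    audits against subject leakage before every fold.
    """
    folds = loso_split(data.subjects)
    per_subject: Dict[str, FoldResult] = {}
    for k, (subject, train_idx, test_idx) in enumerate(folds):
        if set(data.subjects[train_idx]) & set(data.subjects[test_idx]):
            raise RuntimeError("subject leakage between train and test fold")
        fold_seed = (train_cfg.seed + 1009 * (k + 1)) % (2**31)
        model = build_two_stream_model(
            net_cfg, loss_cfg, data.seq_len, data.frame_hw, seed=fold_seed)
        fold_train_cfg = TrainConfig(
            learning_rate=train_cfg.learning_rate, epochs=train_cfg.epochs,
            batch_size=train_cfg.batch_size, seed=fold_seed)
        history = train(model, data.ofi[train_idx], data.mhi[train_idx],
                        data.labels[train_idx], fold_train_cfg)
        pred = predict(model, data.ofi[test_idx], data.mhi[test_idx])
        y_true = data.labels[test_idx]
        y_pred = np.argmax(pred.fused, axis=1)
        cm = confusion_matrix(y_true, y_pred, net_cfg.n_classes)
        macro_p, macro_r, macro_f1 = macro_metrics(cm)
        acc_ofi = float(np.mean(np.argmax(pred.ofi, axis=1) == y_true))
        acc_mhi = float(np.mean(np.argmax(pred.mhi, axis=1) == y_true))
        per_subject[subject] = FoldResult(
            subject_id=subject, cm=cm, accuracy=accuracy(cm),
            macro_precision=macro_p, macro_recall=macro_r, macro_f1=macro_f1,
            accuracy_ofi=acc_ofi, accuracy_mhi=acc_mhi,
            attention_ofi=pred.attention_ofi, attention_mhi=pred.attention_mhi,
            y_true=y_true, y_pred=y_pred, history=history,
        )
        if progress is not None:
            progress(f"fold {k + 1}/{len(folds)} subject={subject} "
                     f"acc={per_subject[subject].accuracy:.3f}")
    result = LOSOResult(per_subject=per_subject, summary={})
    result.summary = _summarise(result.to_frame())
    return result
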