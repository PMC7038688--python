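"""Synthetic multi-subject face-motion video generator.

Emulates the structure of calibrated pain-elicitation video studies so the
whole pipeline — motion representations, two-stream training, LOSO
evaluation — can be exercised without access to clinical datasets: several
subjects, a balanced number of trials per class, and two classes
(baseline-like vs pain-like) that differ in the amplitude of a localised
facial movement peaking late in the clip.

Each trial renders a procedural face (smooth elliptical head with
Gaussian eye, brow and mouth blobs) whose brow and mouth displace over
time with a class- and subject-scaled amplitude.  The motion envelope
rises from zero to its apex at a configurable fraction of the clip and
then relaxes only partially, mimicking a facial expression that builds to
a peak and lingers.  Per-subject expressiveness multipliers and an
optional fraction of "non-responders" (subjects whose two classes share
the baseline amplitude) reproduce the inter-individual variability such
studies report.  Additive Gaussian fixed-pattern noise (a per-trial
static sensor pattern) models the dominant noise of well-lit, denoised
studio video; purely temporal per-pixel flicker is deliberately not
modelled, because the motion mask thresholds raw single-count intensity
changes and has no noise immunity — the clinical pipelines this emulates
operate on video whose static regions are temporally stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from painstream.video_io import FrameSequence, write_frame_sequence

__all__ = [
    "SyntheticConfig", "SubjectParams", "SyntheticDataset",
    "generate_trial", "generate_dataset", "write_dataset",
    "difference_energy", "baseline_threshold_accuracy",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and rendering parameters for the generator.

    ``motion_amplitude`` is the peak displacement (pixels at the default
    48 px frame scale) of the mouth/brow blobs per class; ``apex_position``
    is the fraction of the clip at which the movement peaks (late by
    default, so attention should favour late frames); ``subject_effect_sd``
    is the log-scale spread of per-subject expressiveness multipliers;
    ``noise_sd`` scales the static per-trial sensor-noise pattern;
    ``nonresponder_fraction`` makes that share of subjects move with the
    baseline amplitude in both classes.
    """

    n_subjects: int = 8
    trials_per_class: int = 10
    n_classes: int = 2
    frame_size: int = 48
    fps: float = 8.0
    clip_s: float = 4.0
    motion_amplitude: Tuple[float, float] = (0.5, 3.0)
    apex_position: float = 0.7
    residual_level: float = 0.4
    subject_effect_sd: float = 0.15
    noise_sd: float = 2.0
    nonresponder_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.apex_position < 1.0:
            raise ValueError("apex_position must lie in (0, 1)")
        if min(self.motion_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise ValueError("nonresponder_fraction must lie in [0, 1]")
        if self.n_classes != len(self.motion_amplitude):
            raise ValueError("one amplitude per class required")

    @property
    def frames_per_clip(self) -> int:
        return int(round(self.fps * self.clip_s))


@dataclass(frozen=True)
class SubjectParams:
    subject_id: str
    expressiveness: float  # multiplicative amplitude factor
    responder: bool


@dataclass
class SyntheticDataset:
    trials: List[FrameSequence]
    manifest: pd.DataFrame
    subject_params: List[SubjectParams]
    config: SyntheticConfig


def _motion_envelope(n_frames: int, apex_position: float,
                     residual_level: float) -> np.ndarray:
    """Amplitude envelope over the clip: 0 at the first frame, smooth rise
    to 1 at the apex, then partial relaxation toward ``residual_level``."""
    t = np.linspace(0.0, 1.0, n_frames)
    e = np.empty(n_frames)
    rise = t <= apex_position
    x = np.where(apex_position > 0, t / apex_position, 1.0)
    e[rise] = (3.0 * x[rise] ** 2 - 2.0 * x[rise] ** 3)  # smoothstep
    fall = ~rise
    y = (t[fall] - apex_position) / max(1.0 - apex_position, 1e-9)
    e[fall] = 1.0 - (1.0 - residual_level) * y
    e[0] = 0.0
    return e


def _render_face(size: int, mouth_shift: float, brow_shift: float) -> np.ndarray:
    """Render one grayscale face frame (float, [0, 255]).

    ``mouth_shift`` lowers and widens the mouth blob; ``brow_shift``
    lowers the brow blobs — both in pixels at the given frame scale.
    """
    s = size / 48.0  # geometry defined at the 48 px reference scale
    ax = np.arange(size) - (size - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)  # yy: downward positive

    def blob(cx, cy, sx, sy, depth):
        return depth * np.exp(-(((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2) / 2.0)

    # head: flat-topped ellipse
    r2 = (xx / (16.0 * s)) ** 2 + (yy / (20.0 * s)) ** 2
    img = 170.0 * np.exp(-r2 ** 3) + 20.0
    # eyes
    img += blob(-7.0 * s, -5.0 * s, 2.2 * s, 1.6 * s, -70.0)
    img += blob(+7.0 * s, -5.0 * s, 2.2 * s, 1.6 * s, -70.0)
    # brows (displaced downward when frowning)
    img += blob(-7.0 * s, -9.5 * s + brow_shift * s, 3.2 * s, 1.1 * s, -55.0)
    img += blob(+7.0 * s, -9.5 * s + brow_shift * s, 3.2 * s, 1.1 * s, -55.0)
    # nose
    img += blob(0.0, 2.0 * s, 1.4 * s, 3.0 * s, -25.0)
    # mouth (drops and opens with motion)
    img += blob(0.0, 11.0 * s + mouth_shift * s, 5.5 * s,
                (1.6 + 0.45 * mouth_shift) * s, -85.0)
    return np.clip(img, 0.0, 255.0)


def generate_trial(cfg: SyntheticConfig, subject: SubjectParams, label: int,
                   rng: np.random.Generator, trial_id: str = "t0"
                   ) -> FrameSequence:
    """Render one labelled clip for one subject."""
    n = cfg.frames_per_clip
    amp_class = (cfg.motion_amplitude[label] if subject.responder
                 else cfg.motion_amplitude[0])
    amp = amp_class * subject.expressiveness * float(rng.lognormal(0.0, 0.1))
    envelope = _motion_envelope(n, cfg.apex_position, cfg.residual_level)
    # static per-trial sensor pattern; cancelled by first-frame differencing
    pattern = rng.normal(0.0, cfg.noise_sd,
                         (cfg.frame_size, cfg.frame_size))
    frames = np.empty((n, cfg.frame_size, cfg.frame_size), dtype=np.uint8)
    for t in range(n):
        d = amp * envelope[t]
        img = _render_face(cfg.frame_size, mouth_shift=d, brow_shift=0.6 * d)
        frames[t] = np.clip(np.rint(img + pattern), 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps=cfg.fps,
                         subject_id=subject.subject_id, trial_id=trial_id,
                         label=label)


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full balanced dataset: every subject contributes
    ``trials_per_class`` clips of every class.  Deterministic in
    ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_nonresponders = int(round(cfg.nonresponder_fraction * cfg.n_subjects))
    subjects = []
    for i in range(cfg.n_subjects):
        subjects.append(SubjectParams(
            subject_id=f"s{i:02d}",
            expressiveness=float(rng.lognormal(0.0, cfg.subject_effect_sd)),
            responder=i >= n_nonresponders,
        ))
    trials: List[FrameSequence] = []
    rows = []
    for subj in subjects:
        for label in range(cfg.n_classes):
            for k in range(cfg.trials_per_class):
                trial_id = f"{subj.subject_id}_c{label}_r{k:02d}"
                trials.append(generate_trial(cfg, subj, label, rng, trial_id))
                rows.append({
                    "subject_id": subj.subject_id, "trial_id": trial_id,
                    "label": label, "path": "", "fps": cfg.fps, "onset_s": 0.0,
                })
    manifest = pd.DataFrame(rows)
    return SyntheticDataset(trials=trials, manifest=manifest,
                            subject_params=subjects, config=cfg)


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """Write every trial as a PNG frame directory plus a manifest CSV;
    returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    for i, seq in enumerate(dataset.trials):
        trial_dir = out_dir / seq.subject_id / seq.trial_id
        write_frame_sequence(seq, trial_dir)
        manifest.loc[i, "path"] = str(trial_dir)
    path = out_dir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def difference_energy(seq: FrameSequence) -> float:
    """Mean absolute intensity change against the first frame — a simple
    motion-energy statistic used as a baseline classifier feature."""
    frames = seq.frames.astype(np.float64)
    if frames.ndim == 4:
        frames = frames.mean(axis=-1)
    return float(np.mean(np.abs(frames[1:] - frames[0])))


def baseline_threshold_accuracy(dataset: SyntheticDataset,
                                responders_only: bool = True) -> float:
    """Training accuracy of a one-feature threshold classifier on the
    motion energy, the sanity baseline for class separability."""
    responder_ids = {s.subject_id for s in dataset.subject_params if s.responder}
    pairs = [(difference_energy(t), t.label) for t in dataset.trials
             if not responders_only or t.subject_id in responder_ids]
    if not pairs:
        raise ValueError("no trials selected")
    energies = np.array([e for e, _ in pairs])
    labels = np.array([l for _, l in pairs])
    # best threshold over the observed energies (train accuracy)
    candidates = np.unique(energies)
    best = 0.0
    for thr in candidates:
        acc = max(np.mean((energies >= thr) == labels),
                  np.mean((energies < thr) == labels))
        best = max(best, float(acc))
    return best
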