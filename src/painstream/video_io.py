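"""Loading, segmentation, grayscale conversion and temporal subsampling of
face-video frame sequences.

Clips are handled as :class:`FrameSequence` objects: a dense array of
frames plus the frame rate and subject/trial/label metadata.  The analysis
windows used throughout the package are defined relative to a stimulus
elicitation onset: a window of ``length_s`` seconds starting ``shift_s``
seconds after the onset (the pain-elicitation protocols this targets use a
4.5 s window shifted 4 s past onset, which at 25 fps gives 113 frames and
at 30 fps gives 135).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FrameSequence", "WindowSpec", "load_frame_sequence", "write_frame_sequence",
    "to_grayscale", "extract_window", "subsample", "window_frame_count",
    "round_half_up", "read_manifest", "protocol_sample_count",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

# BT.601 luma weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (112.5 -> 113)."""
    return int(math.floor(x + 0.5))


@dataclass
class FrameSequence:
    """An ordered stack of equally sized frames with acquisition metadata.

    ``frames`` has shape ``(t, h, w)`` for grayscale or ``(t, h, w, 3)`` for
    color.  ``value_range`` records whether pixel intensities live in the
    8-bit integer range ``[0, 255]`` or are normalised to ``[0, 1]``.
    """

    frames: np.ndarray
    fps: float
    subject_id: str = ""
    trial_id: str = ""
    label: Optional[int] = None
    value_range: str = "uint8"  # "uint8" -> [0, 255], "unit" -> [0, 1]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"frames must be (t,h,w) or (t,h,w,c); got shape {self.frames.shape}"
            )
        if self.frames.ndim == 4 and self.frames.shape[-1] not in (1, 3):
            raise ValueError("color frames must have 1 or 3 planes")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.frames) == 0:
            raise ValueError("a FrameSequence needs at least one frame")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def is_grayscale(self) -> bool:
        return self.frames.ndim == 3 or self.frames.shape[-1] == 1

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:3]


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: ``length_s`` seconds starting ``shift_s`` seconds
    after the elicitation onset ``onset_s``."""

    length_s: float = 4.5
    shift_s: float = 4.0
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")
        if self.shift_s < 0:
            raise ValueError("shift_s must be non-negative")


def load_frame_sequence(
    path,
    fps: float,
    subject_id: str = "",
    trial_id: str = "",
    label: Optional[int] = None,
) -> FrameSequence:
    """Load a clip from a directory of image frames (lexicographic order)
    or from a video file an installed imageio plugin can decode."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"no image frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = np.stack(list(iio.imiter(path)))
        if len(frames) == 0:
            raise ValueError(f"no frames decoded from {path}")
    return FrameSequence(
        frames=frames, fps=fps, subject_id=subject_id, trial_id=trial_id,
        label=label,
    )


def write_frame_sequence(seq: FrameSequence, out_dir) -> list:
    """Write a sequence as zero-padded 8-bit PNG frames; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seq.value_range == "unit":
        data = np.clip(np.rint(seq.frames * 255.0), 0, 255).astype(np.uint8)
    else:
        data = np.clip(np.rint(seq.frames), 0, 255).astype(np.uint8)
    paths = []
    for i, frame in enumerate(data):
        p = out_dir / f"frame_{i:05d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def to_grayscale(seq: FrameSequence) -> FrameSequence:
    """Convert color frames to single-plane grayscale.

    Uses the BT.601 luma combination 0.299 R + 0.587 G + 0.114 B, rounded
    half-up for 8-bit input.  Grayscale input is returned unchanged.
    """
    if seq.is_grayscale:
        if seq.frames.ndim == 4:  # (t,h,w,1) -> (t,h,w)
            return replace(seq, frames=seq.frames[..., 0])
        return seq
    if seq.frames.shape[-1] != 3:
        raise ValueError(
            f"unsupported plane count {seq.frames.shape[-1]}; expected 1 or 3"
        )
    luma = seq.frames.astype(np.float64) @ _LUMA
    if seq.value_range == "uint8":
        luma = np.floor(luma + 0.5).astype(seq.frames.dtype if
                                           np.issubdtype(seq.frames.dtype, np.integer)
                                           else np.uint8)
    return replace(seq, frames=luma)


def window_frame_count(length_s: float, fps: float) -> int:
    """Number of frames covering ``length_s`` seconds at ``fps`` (half-up:
    4.5 s at 25 fps -> 113; at 30 fps -> 135)."""
    return round_half_up(length_s * fps)


def extract_window(seq: FrameSequence, spec: WindowSpec) -> FrameSequence:
    """Slice the analysis window out of a clip.

    The window starts ``round_half_up((onset_s + shift_s) * fps)`` frames in
    and spans ``window_frame_count(length_s, fps)`` frames, half-open.
    """
    start = round_half_up((spec.onset_s + spec.shift_s) * seq.fps)
    n = window_frame_count(spec.length_s, seq.fps)
    if start + n > len(seq):
        raise ValueError(
            f"window [{start}, {start + n}) exceeds sequence of length {len(seq)}"
        )
    return replace(seq, frames=seq.frames[start:start + n])


def subsample(seq: FrameSequence, stride: int) -> FrameSequence:
    """Keep frames at indices 0, stride, 2*stride, ... (length ceil(n/stride))."""
    if stride < 1 or int(stride) != stride:
        raise ValueError("stride must be a positive integer")
    return replace(seq, frames=seq.frames[::int(stride)])


def read_manifest(path) -> pd.DataFrame:
    """Read a dataset manifest CSV with columns
    subject_id, trial_id, label, path, fps, onset_s."""
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    required = {"subject_id", "trial_id", "label", "path", "fps", "onset_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def protocol_sample_count(
    n_subjects: int,
    elicitations_per_level: int,
    n_levels: int,
    include_baseline: bool = True,
    n_sessions: int = 1,
) -> int:
    """Total trials in a calibrated-stimulation study design.

    ``n_levels`` stimulus intensities, each elicited
    ``elicitations_per_level`` times per subject and session, plus (if
    ``include_baseline``) an equal number of baseline windows.  E.g. 87
    subjects x 20 elicitations x (4 levels + baseline) = 8700 samples; 40
    subjects x 30 x (3 + 1) x 2 arms = 9600.
    """
    conditions = n_levels + (1 if include_baseline else 0)
    return n_subjects * elicitations_per_level * conditions * n_sessions
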