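"""Motion representations: Motion History Image (MHI) sequences and
color-encoded dense Optical Flow Image (OFI) sequences.

An MHI is a scalar image in which each pixel encodes how recently motion
occurred at that location: whenever the absolute intensity difference
between the current frame and a reference frame reaches a threshold xi,
the pixel is set to the temporal extent tau; otherwise it decays by delta
per step (floored at zero).  Saving the image produced at every step of
this recursion turns a clip into a sequence of MHIs.

An OFI encodes a dense optical-flow field as a color image: the flow
direction maps to hue and the flow magnitude to brightness, at full
saturation.  The flow field itself is estimated with an established dense
solver (iterative Lucas–Kanade from scikit-image); the encoding, not the
solver, is what this module owns.

Both representations are computed against a reference frame, by default
the very first frame of the clip, so that frame t's image accumulates all
motion since the clip start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.color import hsv2rgb
from skimage.registration import optical_flow_ilk

from painstream.video_io import FrameSequence

__all__ = [
    "MHIParams", "MHISequence", "FlowField", "FlowConfig", "OFISequence",
    "frame_difference", "update_mask", "mhi_step", "mhi_sequence",
    "dense_flow", "flow_to_image", "ofi_sequence",
    "mhi_to_network_input", "ofi_to_network_input",
]


@dataclass(frozen=True)
class MHIParams:
    """MHI recursion parameters.

    tau: temporal extent (maximum pixel value; conventionally the clip
    length in frames).  xi: motion-detection threshold on the absolute
    frame difference, inclusive.  delta: per-step decay.  reference_mode
    selects whether differences are taken against the clip's first frame
    or the immediately preceding frame.
    """

    tau: float
    xi: float = 1.0
    delta: float = 1.0
    reference_mode: str = "first_frame"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.xi < 0:
            raise ValueError("xi must be non-negative")
        if self.reference_mode not in ("first_frame", "previous_frame"):
            raise ValueError(f"unknown reference_mode {self.reference_mode!r}")


@dataclass
class MHISequence:
    """Stack of per-step MHIs, shape (n-1, h, w); values in [0, tau]."""

    images: np.ndarray
    params: MHIParams

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class FlowField:
    """Dense optical flow: u = dx/dt (columns, rightward positive) and
    v = dy/dt (rows, downward positive), in pixels per frame step."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def angle(self) -> np.ndarray:
        return np.arctan2(self.v, self.u)


@dataclass(frozen=True)
class FlowConfig:
    """Dense-flow solver settings (iterative Lucas–Kanade): integration
    window radius in pixels, number of warp iterations, and Gaussian vs
    uniform weighting of the window."""

    radius: int = 7
    num_warp: int = 10
    gaussian: bool = False

    def __post_init__(self) -> None:
        if self.radius < 1 or self.num_warp < 1:
            raise ValueError("radius and num_warp must be >= 1")


@dataclass
class OFISequence:
    """Stack of color flow encodings, shape (n-1, h, w, 3), uint8 RGB."""

    images: np.ndarray
    encoding: str = "hsv_angle_magnitude"
    normalisation: str = "per_sequence"

    def __len__(self) -> int:
        return len(self.images)


def frame_difference(frame_t: np.ndarray, frame_ref: np.ndarray) -> np.ndarray:
    """Elementwise absolute intensity difference |I_t - I_ref|."""
    frame_t = np.asarray(frame_t)
    frame_ref = np.asarray(frame_ref)
    if frame_t.shape != frame_ref.shape:
        raise ValueError(
            f"frame shapes differ: {frame_t.shape} vs {frame_ref.shape}"
        )
    return np.abs(frame_t.astype(np.float64) - frame_ref.astype(np.float64))


def update_mask(diff: np.ndarray, xi: float) -> np.ndarray:
    """Binary motion mask: 1 where the difference reaches xi (inclusive)."""
    return (np.asarray(diff) >= xi).astype(np.uint8)


def mhi_step(h_prev: np.ndarray, psi: np.ndarray, params: MHIParams) -> np.ndarray:
    """One MHI update: tau where the mask fires, else decay by delta,
    floored at zero."""
    h_prev = np.asarray(h_prev, dtype=np.float64)
    psi = np.asarray(psi)
    if h_prev.shape != psi.shape:
        raise ValueError("mask and history shapes differ")
    decayed = np.maximum(0.0, h_prev - params.delta)
    return np.where(psi == 1, float(params.tau), decayed)


def mhi_sequence(seq: FrameSequence, params: Optional[MHIParams] = None) -> MHISequence:
    """Run the MHI recursion over a grayscale clip, keeping every step.

    Returns n-1 images for an n-frame clip (one per frame t = 1..n-1).
    With the default parameters, tau equals the clip length in frames and
    xi = 1 so that any single-count intensity fluctuation registers as
    motion.  The history starts at zero everywhere.
    """
    if not seq.is_grayscale:
        raise ValueError("mhi_sequence expects a grayscale sequence")
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 frames to compute motion")
    if params is None:
        params = MHIParams(tau=float(n))
    frames = seq.frames if seq.frames.ndim == 3 else seq.frames[..., 0]
    h = np.zeros(frames.shape[1:], dtype=np.float64)
    out = np.empty((n - 1,) + frames.shape[1:], dtype=np.float64)
    for t in range(1, n):
        ref = frames[0] if params.reference_mode == "first_frame" else frames[t - 1]
        psi = update_mask(frame_difference(frames[t], ref), params.xi)
        h = mhi_step(h, psi, params)
        out[t - 1] = h
    return MHISequence(images=out, params=params)


def dense_flow(
    frame_ref: np.ndarray,
    frame_t: np.ndarray,
    config: FlowConfig = FlowConfig(),
) -> FlowField:
    """Estimate the dense flow carrying features of ``frame_ref`` to their
    positions in ``frame_t``.

    Deterministic for fixed inputs and config.  A feature that moved two
    pixels rightward between the frames yields u ~ +2 at its location.
    """
    frame_ref = np.asarray(frame_ref, dtype=np.float32)
    frame_t = np.asarray(frame_t, dtype=np.float32)
    if frame_ref.shape != frame_t.shape:
        raise ValueError("frames must share a shape")
    if frame_ref.ndim != 2:
        raise ValueError("dense_flow expects 2-D grayscale frames")
    flow = optical_flow_ilk(
        frame_ref, frame_t,
        radius=config.radius, num_warp=config.num_warp,
        gaussian=config.gaussian,
    )
    return FlowField(u=flow[1], v=flow[0])


def flow_to_image(
    flow: FlowField,
    max_magnitude: Optional[float] = None,
) -> np.ndarray:
    """Encode a flow field as an RGB image: hue <- direction, brightness <-
    magnitude (normalised by ``max_magnitude``, default the field's own
    maximum), full saturation.  Zero flow maps to black.
    """
    u, v = np.asarray(flow.u), np.asarray(flow.v)
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("flow field contains NaN or Inf")
    mag = np.hypot(u, v)
    ang = np.arctan2(v, u)  # (-pi, pi]
    hue = (ang % (2.0 * np.pi)) / (2.0 * np.pi)
    scale = float(np.max(mag)) if max_magnitude is None else float(max_magnitude)
    value = mag / scale if scale > 0 else np.zeros_like(mag)
    value = np.clip(value, 0.0, 1.0)
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    rgb = hsv2rgb(hsv)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def ofi_sequence(
    seq: FrameSequence,
    config: FlowConfig = FlowConfig(),
    normalisation: str = "per_sequence",
) -> OFISequence:
    """Color-encode the dense flow between the first frame and every later
    frame of a grayscale clip (n-1 images for n frames).

    ``per_sequence`` normalisation (default) scales brightness by the
    maximum magnitude across the whole clip, preserving the ordering of
    velocities across frames; ``per_frame`` rescales each image by its own
    maximum.
    """
    if normalisation not in ("per_sequence", "per_frame"):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    if not seq.is_grayscale:
        raise ValueError("ofi_sequence expects a grayscale sequence")
    n = len(seq)
    if n < 2:
        raise ValueError("need at least 2 frames to compute motion")
    frames = seq.frames if seq.frames.ndim == 3 else seq.frames[..., 0]
    fields = [dense_flow(frames[0], frames[t], config) for t in range(1, n)]
    if normalisation == "per_sequence":
        global_max = max((float(np.max(f.magnitude)) for f in fields), default=0.0)
        images = [flow_to_image(f, max_magnitude=global_max if global_max > 0 else None)
                  for f in fields]
    else:
        images = [flow_to_image(f) for f in fields]
    return OFISequence(images=np.stack(images), normalisation=normalisation)


def mhi_to_network_input(mhi: MHISequence) -> np.ndarray:
    """Rescale an MHI stack to [0, 1] floats with a trailing channel axis:
    (l, h, w, 1), ready for the MHI stream."""
    return (mhi.images / float(mhi.params.tau))[..., None].astype(np.float32)


def ofi_to_network_input(ofi: OFISequence) -> np.ndarray:
    """Rescale an OFI stack to [0, 1] floats, shape (l, h, w, 3)."""
    return (ofi.images / 255.0).astype(np.float32)
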