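"""Glue between raw clips and network-ready two-stream tensors.

For each trial: grayscale conversion, optional analysis-window
extraction, MHI and OFI computation over the full window against the
first frame, then temporal subsampling of the representation stacks.
Every frame position t = 0..n-1 carries a representation — the one at
t = 0 is identically zero (no motion has occurred yet) — so an n-frame
window subsampled with stride k yields ceil(n/k) representation frames
(113 -> 57 at stride 2, 135 -> 45 at stride 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from painstream.motion import (
    FlowConfig, MHIParams, mhi_sequence, mhi_to_network_input, ofi_sequence,
    ofi_to_network_input,
)
from painstream.synthetic import SyntheticDataset
from painstream.video_io import FrameSequence, WindowSpec, extract_window, to_grayscale

__all__ = ["preprocess_trial", "TwoStreamTensors", "prepare_two_stream_tensors"]


def preprocess_trial(
    seq: FrameSequence,
    stride: int = 2,
    window: Optional[WindowSpec] = None,
    mhi_params: Optional[MHIParams] = None,
    flow_config: FlowConfig = FlowConfig(),
    normalisation: str = "per_sequence",
) -> Tuple[np.ndarray, np.ndarray]:
    """One trial -> (mhi_input (l,h,w,1), ofi_input (l,h,w,3)), both
    float32 in [0, 1], with l = ceil(window_frames / stride)."""
    gray = to_grayscale(seq)
    if window is not None:
        gray = extract_window(gray, window)
    mhi = mhi_sequence(gray, mhi_params)
    ofi = ofi_sequence(gray, flow_config, normalisation)
    mhi_in = mhi_to_network_input(mhi)
    ofi_in = ofi_to_network_input(ofi)
    zero_m = np.zeros((1,) + mhi_in.shape[1:], dtype=np.float32)
    zero_o = np.zeros((1,) + ofi_in.shape[1:], dtype=np.float32)
    mhi_full = np.concatenate([zero_m, mhi_in])[::stride]
    ofi_full = np.concatenate([zero_o, ofi_in])[::stride]
    return mhi_full, ofi_full


@dataclass
class TwoStreamTensors:
    """Network-ready dataset: OFI (n, l, h, w, 3) and MHI (n, l, h, w, 1)
    stacks with aligned labels and subject ids."""

    ofi: np.ndarray
    mhi: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray

    @property
    def seq_len(self) -> int:
        return self.ofi.shape[1]

    @property
    def frame_hw(self) -> Tuple[int, int]:
        return self.ofi.shape[2], self.ofi.shape[3]


def prepare_two_stream_tensors(
    dataset: SyntheticDataset,
    stride: int = 2,
    window: Optional[WindowSpec] = None,
    flow_config: FlowConfig = FlowConfig(),
    normalisation: str = "per_sequence",
) -> TwoStreamTensors:
    """Preprocess every trial of an in-memory dataset into stacked
    two-stream tensors."""
    mhis: List[np.ndarray] = []
    ofis: List[np.ndarray] = []
    for seq in dataset.trials:
        m, o = preprocess_trial(seq, stride=stride, window=window,
                                flow_config=flow_config,
                                normalisation=normalisation)
        mhis.append(m)
        ofis.append(o)
    labels = np.array([t.label for t in dataset.trials], dtype=np.int64)
    subjects = np.array([t.subject_id for t in dataset.trials])
    return TwoStreamTensors(ofi=np.stack(ofis), mhi=np.stack(mhis),
                            labels=labels, subjects=subjects)
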