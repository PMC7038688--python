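# Methods

## Problem setting

The package classifies short face-video clips into pain-related classes
(binary by default: baseline vs painful stimulation). Clips are assumed to
be face-cropped, aligned and resampled to a fixed spatial size upstream
(external face-analysis tooling; out of scope here). The model operates
not on raw frames but on two motion representations computed per clip, and
is evaluated subject-disjointly (leave-one-subject-out), which is the
clinically meaningful regime: a deployed system meets unseen people.

## Motion representations

**Analysis window.** A trial's window is `length_s` seconds starting
`shift_s` seconds after the stimulus onset. Frame counts are rounded
half-up from seconds × fps (4.5 s at 25 fps → 113 frames, at 30 fps → 135),
and temporal subsampling keeps indices 0, k, 2k, … (113 at stride 2 → 57
positions; 135 at stride 3 → 45). All indexing is 0-based with half-open
windows.

**MHI.** Parameters: temporal extent τ (default: the window length in
frames, so the whole window's history fits in one image), threshold ξ
(default 1 — a single 8-bit intensity count registers as motion), decay δ
(default 1, the classic convention; the source material for this design
leaves δ open), reference mode (default `first_frame`: differences are
taken against the clip's first frame, so motion accumulates relative to
the neutral start; `previous_frame` gives the classic consecutive-frame
dialect). The recursion starts from an all-zero history, and every step's
image is kept.

**OFI.** Dense flow between frame 0 and frame t from scikit-image's
iterative Lucas–Kanade estimator (`radius=7`, `num_warp=10`, uniform
window — exposed in `FlowConfig`). Encoding: hue = flow angle mapped onto
[0, 1), saturation = 1, value = magnitude normalised by the per-sequence
maximum (default) so that velocity ordering across frames survives;
per-frame normalisation is available but discards that ordering. Zero
flow maps to black. The solver choice is interchangeable by design — the
representation contract is only that (u, v) is a dense per-pixel estimate,
deterministic for fixed inputs.

**Representation positions.** Every frame position t = 0..n−1 of a window
carries one representation frame; position 0 is identically zero for both
streams (the history starts empty, and the flow of frame 0 against itself
vanishes). This convention makes the subsampled representation length
equal ceil(n/stride) and reproduces the printed tensor lengths above.
Representations are computed on the full window first and subsampled
afterwards, so frame 0 remains the global reference. Network inputs are
scaled to [0, 1]: MHI by 1/τ, OFI by 1/255.

## Network

Per stream: a time-distributed embedder — conv blocks (2×8, 2×16, 3×32,
3×64 filters), 3×3 kernels, stride 1, same padding, elu activations, each
block closed by 2×2/2×2 max pooling then batch normalisation, and a final
flatten (100×100 input → 2304 features; 48×48 → 576) — then a BiLSTM with
64 units per direction (gates: logistic sigmoid; candidate: tanh; the
forget-gate bias starts at 1), frame attention (a single learned linear
functional per position, elu with α = 1, softmax across positions, convex
pooling), and a classifier Dropout(0.25) → Dense(64, elu) → Dropout(0.25)
→ Dense(c, softmax).

Fusion: the two stream probability vectors are combined convexly; the two
coefficients are the softmax of two free scalars (initialised equal), so
the sum-to-one constraint holds at initialisation and after every
optimiser update by construction. The joint loss is
λ_ofi·CE_ofi + λ_mhi·CE_mhi + λ_agg·CE_agg with defaults 0.2/0.2/0.6 —
the aggregation head dominates so the fusion weights receive a strong
signal. Cross-entropy uses a 1e-7 floor inside the log. Per-stream losses
use the same labels as the fused loss (single task, multiple heads).
Prediction uses the aggregation output; per-stream probabilities and both
streams' attention weights are exposed for analysis.

Implementation notes: the whole stack is float32 NumPy. Convolutions are
evaluated as nine shifted GEMMs with per-layer scratch buffers (the
training loop is memory-bandwidth-bound; a glibc mallopt keeps large
temporaries out of mmap). Backpropagation through time is explicit;
every layer's analytic gradient is checked against central finite
differences in the test suite. Max-pool gradients go to the first window
cell attaining the maximum. Weight initialisation: He (fan-in) for
convolutions, Glorot uniform elsewhere, all from a generator seeded per
model; dropout and batch shuffling use separately derived seeds, so a
(seed, config) pair reproduces a run bit for bit. Batch normalisation
keeps running statistics with momentum 0.9 for inference.

One presentation quirk of the source equations is resolved as a typo: the
cell-candidate input weight multiplies x_t (consistent with the other
three gates), and the attention functional maps each hidden state to a
single scalar score.

## Training protocol

End-to-end Adam, fixed epoch count, no early stopping, no validation
split, final-epoch weights. Full-scale reference settings: learning rate
1e-5, 20 epochs, batch 40–60 (dataset-dependent). The desk-scale study
shipped with the package (8 subjects × 20 trials of 48×48/16-position
clips; 140 training trials per fold) uses learning rate 1e-3, 4 epochs,
batch 20: with two orders of magnitude less data per fold, the reference
rate under-trains badly, while at 1e-3 the joint loss reaches ~1e-4 within
3 epochs; one extra epoch is kept as margin. This schedule was fixed from
training-loss behaviour on a single fold before the acceptance study was
run.

## Evaluation

Confusion matrices accumulate per fold; accuracy = trace/total. Macro
precision and recall average the per-class ratios; macro F1 is the
harmonic mean *of the two macro averages* — deliberately not the mean of
per-class F1 scores, which differs on asymmetric matrices. A class with
an empty denominator contributes 0 with a warning: subjects who do not
visibly react produce exactly this degenerate case, so it is handled, not
raised. Paired per-subject metrics are compared with a two-sided Wilcoxon
signed-rank test (zero differences dropped; exact null below 25 non-zero
pairs, normal approximation above). Attention profiles pool the per-frame
weights of test-fold sequences only and report mean/median/quartiles per
position plus a min–max-normalised mean curve.

## Synthetic data

The generator emulates the structure of calibrated heat-pain video
studies: `n_subjects` subjects, balanced trials per class, fixed clip
length and frame rate. Each trial renders a procedural face (flat-topped
elliptical head, Gaussian eye/brow/nose/mouth blobs) whose mouth drops
and widens and whose brows lower by `amplitude × envelope(t)` pixels. The
envelope is 0 at the first frame, rises smoothly to 1 at
`apex_position` (default 0.7 — late, as pain expressions build), then
relaxes to `residual_level` (default 0.4): expressions linger rather than
vanish, keeping late frames informative. Class difference is purely the
peak amplitude (defaults 0.5 px baseline vs 3.0 px pain-like at the 48 px
scale — a clearly separable regime; a pixel-energy threshold classifier
reaches >80 % on responders, which the tests assert). Per-subject
expressiveness is lognormal (σ = 0.15), per-trial amplitude jitter
lognormal (σ = 0.1), and a configurable fraction of non-responders moves
with the baseline amplitude in both classes.

**Noise model.** Sensor noise is a per-trial *static* Gaussian pattern
(default σ = 2 counts) added to every frame, not per-frame flicker. This
is deliberate: with ξ = 1, first-frame referencing and slow decay, any
temporally independent pixel noise above ~0.2 counts fires the motion
mask across the whole frame within a few steps and saturates every MHI —
at any noise level, so it is a structural property of the representation,
not a tuning matter. The fixed pattern preserves what matters for the
tests (seeded determinism, distinct noise per seed, a null dataset when
amplitudes coincide) and models denoised, well-lit studio video whose
static regions are temporally stable; it also gives the flow solver
realistic texture. Consequently, passing tests say nothing about
robustness to temporal sensor noise, motion blur, illumination change,
head pose or identity appearance — none of which the generator models.
The synthetic faces are far easier than clinical video; the end-to-end
study validates the machinery (representations, training dynamics,
fusion, protocol), not clinical performance.

## Numerical and degenerate-input choices

- Grayscale conversion: BT.601 luma, rounded half-up for 8-bit input.
- Frame-count rounding: half-up (112.5 → 113).
- MHI values are clamped into [0, τ] by construction; the update mask
  threshold is inclusive (D ≥ ξ).
- Flow on textureless input returns finite zeros; NaN flow is rejected at
  encoding time. An all-zero flow sequence encodes to black images.
- Attention scores may be negative (elu ≥ −1); softmax handles them, no
  clamping.
- Fusion weight gradients vanish identically when λ_agg = 0 (verified).
- Wilcoxon with all-zero differences raises rather than fabricating a
  p-value.

## Known limitations

- Fixed-length sequences only; no padding/masking for variable l.
- The fusion weights are two global scalars, not per-class.
- Single-fold-at-a-time training; no parallelism across LOSO folds.
- The NumPy stack targets clarity and CPU-scale problems; it is not a
  general-purpose deep-learning framework (no GPU, no mixed precision,
  no graph optimisations).
- Face detection/alignment is out of scope; inputs are assumed cropped.
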