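"""Motion representations: MHI recursion against a brute-force oracle,
dense-flow sanity on known displacements, and flow color encoding."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from painstream.motion import (
    FlowConfig, FlowField, MHIParams, dense_flow, flow_to_image,
    frame_difference, mhi_sequence, mhi_step, ofi_sequence, update_mask,
)
from painstream.video_io import FrameSequence


def mhi_loop_oracle(frames, params):
    """Naive per-pixel, per-step evaluation of the MHI recursion."""
    n, h, w = frames.shape
    out = np.zeros((n - 1, h, w))
    hist = np.zeros((h, w))
    for t in range(1, n):
        ref = frames[0] if params.reference_mode == "first_frame" else frames[t - 1]
        for y in range(h):
            for x in range(w):
                d = abs(float(frames[t, y, x]) - float(ref[y, x]))
                if d >= params.xi:
                    hist[y, x] = params.tau
                else:
                    hist[y, x] = max(0.0, hist[y, x] - params.delta)
        out[t - 1] = hist
    return out


class TestFrameDifference:
    def test_identical_and_offset_frames(self, rng):
        a = rng.integers(0, 250, size=(5, 5)).astype(np.float64)
        np.testing.assert_array_equal(frame_difference(a, a), np.zeros((5, 5)))
        np.testing.assert_allclose(frame_difference(a + 5, a), np.full((5, 5), 5.0))

    def test_matches_per_pixel_loop(self, rng):
        a = rng.integers(0, 256, size=(4, 4))
        b = rng.integers(0, 256, size=(4, 4))
        expected = np.array([[abs(int(a[i, j]) - int(b[i, j]))
                              for j in range(4)] for i in range(4)])
        np.testing.assert_array_equal(frame_difference(a, b), expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            frame_difference(np.zeros((2, 2)), np.zeros((3, 3)))


class TestUpdateMask:
    def test_threshold_is_inclusive(self):
        d = np.array([[0.0, 0.5], [1.0, 2.0]])
        np.testing.assert_array_equal(update_mask(d, 1.0),
                                      [[0, 0], [1, 1]])

    def test_matches_loop_oracle(self, rng):
        d = rng.random((6, 6)) * 3
        expected = (d >= 1.0).astype(int)
        np.testing.assert_array_equal(update_mask(d, 1.0), expected)


class TestMHIStep:
    def test_all_motion_sets_tau(self):
        p = MHIParams(tau=9, xi=1, delta=1)
        h = mhi_step(np.zeros((3, 3)), np.ones((3, 3)), p)
        np.testing.assert_array_equal(h, np.full((3, 3), 9.0))

    def test_decay_floors_at_zero(self):
        p = MHIParams(tau=9, xi=1, delta=2.0)
        prev = np.array([[9.0, 6.0], [1.0, 0.0]])
        h = mhi_step(prev, np.zeros((2, 2), dtype=int), p)
        np.testing.assert_array_equal(h, [[7.0, 4.0], [0.0, 0.0]])

    def test_hand_worked_decay(self):
        tau, delta = 10.0, 2.0
        p = MHIParams(tau=tau, xi=1, delta=delta)
        prev = np.array([[tau, 3 * delta], [delta / 2, 0.0]])
        h = mhi_step(prev, np.zeros((2, 2), dtype=int), p)
        np.testing.assert_array_equal(h, [[tau - delta, 2 * delta], [0.0, 0.0]])


class TestMHISequence:
    def test_constant_sequence_gives_zero_mhis(self):
        frames = np.full((6, 5, 5), 100, dtype=np.uint8)
        seq = FrameSequence(frames=frames, fps=10.0)
        mhi = mhi_sequence(seq)
        assert len(mhi) == 5
        assert np.all(mhi.images == 0)

    def test_persistent_first_frame_difference_holds_tau(self):
        frames = np.full((8, 4, 4), 50, dtype=np.uint8)
        frames[1:, 2, 2] = 80  # changes at t=1, static afterwards
        seq = FrameSequence(frames=frames, fps=10.0)
        p = MHIParams(tau=7.0, xi=1, delta=1, reference_mode="first_frame")
        mhi = mhi_sequence(seq, p)
        assert np.all(mhi.images[:, 2, 2] == 7.0)

    def test_matches_brute_force_loop_oracle(self, rng):
        frames = rng.integers(0, 4, size=(10, 8, 8)).astype(np.uint8)
        seq = FrameSequence(frames=frames, fps=10.0)
        for mode in ("first_frame", "previous_frame"):
            p = MHIParams(tau=9.0, xi=1.0, delta=1.0, reference_mode=mode)
            got = mhi_sequence(seq, p).images
            want = mhi_loop_oracle(frames.astype(np.float64), p)
            np.testing.assert_array_equal(got, want)

    def test_range_invariant_on_random_stacks(self, rng):
        for _ in range(20):
            frames = rng.integers(0, 256, size=(6, 5, 5)).astype(np.uint8)
            seq = FrameSequence(frames=frames, fps=10.0)
            images = mhi_sequence(seq, MHIParams(tau=5, xi=3, delta=1.5)).images
            assert images.min() >= 0.0 and images.max() <= 5.0

    def test_monotone_decay_without_motion(self):
        tau, delta = 6.0, 1.0
        frames = np.full((10, 3, 3), 10, dtype=np.uint8)
        frames[1, 1, 1] = 200  # single transient (previous-frame mode)
        seq = FrameSequence(frames=frames, fps=10.0)
        p = MHIParams(tau=tau, xi=1, delta=delta, reference_mode="previous_frame")
        traj = mhi_sequence(seq, p).images[:, 1, 1]
        # fires twice (up and back down), then decays to 0 in ceil(tau/delta)
        assert traj[1] == tau
        diffs = np.diff(traj[1:])
        assert np.all(diffs <= 0)
        assert traj[1 + int(np.ceil(tau / delta))] == 0.0

    def test_short_input_raises(self):
        seq = FrameSequence(frames=np.zeros((1, 4, 4), dtype=np.uint8), fps=1.0)
        with pytest.raises(ValueError):
            mhi_sequence(seq)


def _textured_frame(rng, size=48):
    return gaussian_filter(rng.random((size, size)).astype(np.float32), 2)


class TestDenseFlow:
    def test_identical_frames_give_zero_flow(self, rng):
        f = _textured_frame(rng)
        flow = dense_flow(f, f)
        assert np.max(np.abs(flow.u)) < 1e-3
        assert np.max(np.abs(flow.v)) < 1e-3

    def test_known_rightward_shift(self, rng):
        ref = _textured_frame(rng)
        mov = np.roll(ref, 2, axis=1)  # 2 px to the right
        flow = dense_flow(ref, mov)
        assert abs(np.median(flow.u) - 2.0) < 0.5
        assert abs(np.median(flow.v)) < 0.5

    def test_textureless_frames_stay_finite(self):
        f = np.full((32, 32), 128.0, dtype=np.float32)
        flow = dense_flow(f, f + 1.0)
        assert np.isfinite(flow.u).all() and np.isfinite(flow.v).all()

    def test_determinism(self, rng):
        ref, mov = _textured_frame(rng), _textured_frame(rng)
        f1 = dense_flow(ref, mov)
        f2 = dense_flow(ref, mov)
        np.testing.assert_array_equal(f1.u, f2.u)
        np.testing.assert_array_equal(f1.v, f2.v)


class TestFlowToImage:
    def test_zero_flow_is_black(self):
        img = flow_to_image(FlowField(u=np.zeros((4, 4)), v=np.zeros((4, 4))))
        assert img.shape == (4, 4, 3)
        assert np.all(img == 0)

    def test_opposite_directions_equal_brightness_opposite_hue(self):
        u = np.array([[3.0, -3.0]])
        v = np.zeros((1, 2))
        img = flow_to_image(FlowField(u=u, v=v)).astype(int)
        assert img[0, 0].max() == img[0, 1].max()  # same brightness
        # rightward motion -> hue 0 (red); leftward -> hue 0.5 (cyan)
        assert img[0, 0, 0] > img[0, 0, 2]
        assert img[0, 1, 2] > img[0, 1, 0]

    def test_scale_invariance_of_self_normalisation(self, rng):
        u = rng.normal(size=(6, 6))
        v = rng.normal(size=(6, 6))
        a = flow_to_image(FlowField(u=u, v=v))
        b = flow_to_image(FlowField(u=2 * u, v=2 * v))
        np.testing.assert_array_equal(a, b)

    def test_nan_rejected(self):
        u = np.zeros((2, 2))
        u[0, 0] = np.nan
        with pytest.raises(ValueError):
            flow_to_image(FlowField(u=u, v=np.zeros((2, 2))))


class TestOFISequence:
    def test_constant_sequence_gives_black_images(self):
        frames = np.full((5, 32, 32), 90, dtype=np.uint8)
        seq = FrameSequence(frames=frames, fps=10.0)
        ofi = ofi_sequence(seq)
        assert ofi.images.shape == (4, 32, 32, 3)
        assert np.all(ofi.images == 0)

    def test_determinism_bit_identical(self, rng):
        frames = (255 * gaussian_filter(rng.random((4, 32, 32)), 1)).astype(np.uint8)
        seq = FrameSequence(frames=frames, fps=10.0)
        a = ofi_sequence(seq, FlowConfig(), "per_sequence").images
        b = ofi_sequence(seq, FlowConfig(), "per_sequence").images
        np.testing.assert_array_equal(a, b)

    def test_length_contract(self, rng):
        frames = rng.integers(0, 256, size=(6, 32, 32)).astype(np.uint8)
        seq = FrameSequence(frames=frames, fps=10.0)
        assert len(ofi_sequence(seq)) == 5
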