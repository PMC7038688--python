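"""Single-stream network components: embedder shapes and weight sharing,
LSTM cell against a scalar-loop oracle, BiLSTM symmetry, attention
pooling against direct recomputation, classifier normalisation."""

import numpy as np
import pytest

from painstream.attention_net import (
    AttentionNetwork, EmbedderConfig, LSTMCellParams, NetConfig,
    attention_pool, build_embedder, embedded_feature_dim, lstm_cell_step,
)
from painstream.nn import BiLSTM, LSTM, softmax
from painstream.nn.layers import elu


def scalar_loop_lstm_step(x, h_prev, c_prev, p):
    """Eqs of the LSTM cell evaluated one scalar at a time."""
    units, d = p.W_i.shape

    def gate(W, U, b, squash):
        out = np.zeros(units)
        for u in range(units):
            acc = b[u]
            for j in range(d):
                acc += W[u, j] * x[j]
            for j in range(units):
                acc += U[u, j] * h_prev[j]
            out[u] = squash(acc)
        return out

    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    f = gate(p.W_f, p.U_f, p.b_f, sig)
    i = gate(p.W_i, p.U_i, p.b_i, sig)
    g = gate(p.W_c, p.U_c, p.b_c, np.tanh)
    o = gate(p.W_o, p.U_o, p.b_o, sig)
    c = np.array([f[u] * c_prev[u] + i[u] * g[u] for u in range(units)])
    h = np.array([o[u] * np.tanh(c[u]) for u in range(units)])
    return h, c


def random_cell_params(rng, d_in, units):
    m = lambda *s: rng.normal(size=s)
    return LSTMCellParams(
        W_i=m(units, d_in), W_f=m(units, d_in), W_o=m(units, d_in),
        W_c=m(units, d_in),
        U_i=m(units, units), U_f=m(units, units), U_o=m(units, units),
        U_c=m(units, units),
        b_i=m(units), b_f=m(units), b_o=m(units), b_c=m(units),
    )


class TestEmbedder:
    def test_feature_dim_at_paper_scale(self):
        # 100 -> 50 -> 25 -> 12 -> 6 under floor-halving, 6*6*64 = 2304
        assert embedded_feature_dim(EmbedderConfig(), 100, 100) == 2304

    def test_feature_dim_at_desk_scale(self):
        assert embedded_feature_dim(EmbedderConfig(), 48, 48) == 3 * 3 * 64

    def test_ten_conv_layers(self):
        assert EmbedderConfig().n_conv_layers == 10

    def test_identical_frames_share_weights(self, rng):
        net = AttentionNetwork(NetConfig(), (16, 16, 1), seed=3)
        frame = rng.random((1, 16, 16, 1)).astype(np.float32)
        x = np.concatenate([frame, frame])[None]  # (1, 2, 16, 16, 1)
        feats = net.embed_frames(x)
        np.testing.assert_array_equal(feats[0, 0], feats[0, 1])

    def test_batch_and_time_axes_commute(self, rng):
        net = AttentionNetwork(NetConfig(), (16, 16, 1), seed=3)
        x = rng.random((2, 3, 16, 16, 1)).astype(np.float32)
        feats_seq = net.embed_frames(x)
        flat = net.embedder.forward(x.reshape(6, 16, 16, 1))
        np.testing.assert_allclose(feats_seq.reshape(6, -1), flat, atol=1e-6)

    def test_too_small_frames_rejected(self):
        with pytest.raises(ValueError):
            AttentionNetwork(NetConfig(), (8, 8, 1), seed=0)


class TestLSTMCell:
    def test_zero_weights_zero_output(self):
        z = np.zeros
        p = LSTMCellParams(
            W_i=z((2, 3)), W_f=z((2, 3)), W_o=z((2, 3)), W_c=z((2, 3)),
            U_i=z((2, 2)), U_f=z((2, 2)), U_o=z((2, 2)), U_c=z((2, 2)),
            b_i=z(2), b_f=z(2), b_o=z(2), b_c=z(2))
        h, c = lstm_cell_step(np.ones(3), np.zeros(2), np.zeros(2), p)
        np.testing.assert_array_equal(h, np.zeros(2))
        np.testing.assert_array_equal(c, np.zeros(2))

    def test_matches_scalar_loop_oracle(self, rng):
        p = random_cell_params(rng, d_in=3, units=2)
        x, h0, c0 = rng.normal(size=3), rng.normal(size=2), rng.normal(size=2)
        h, c = lstm_cell_step(x, h0, c0, p)
        h_ref, c_ref = scalar_loop_lstm_step(x, h0, c0, p)
        np.testing.assert_allclose(h, h_ref, atol=1e-6)
        np.testing.assert_allclose(c, c_ref, atol=1e-6)

    def test_batched_layer_matches_reference_cell(self, rng):
        """The production batched LSTM layer must agree step by step with
        the reference cell recursion built from the same weights."""
        layer = LSTM(d_in=4, units=3, rng=np.random.default_rng(5))
        p = LSTMCellParams.from_fused(
            layer.wx.value.astype(np.float64),
            layer.wh.value.astype(np.float64),
            layer.b.value.astype(np.float64))
        x = rng.normal(size=(2, 6, 4)).astype(np.float32)
        hs = layer.forward(x)
        for b in range(2):
            h = np.zeros(3)
            c = np.zeros(3)
            for t in range(6):
                h, c = lstm_cell_step(x[b, t].astype(np.float64), h, c, p)
                np.testing.assert_allclose(hs[b, t], h, atol=1e-5)


class TestBiLSTM:
    def test_output_dimension_is_twice_units(self, rng):
        layer = BiLSTM(d_in=5, units=64, rng=np.random.default_rng(0))
        out = layer.forward(rng.normal(size=(1, 4, 5)).astype(np.float32))
        assert out.shape == (1, 4, 128)

    def test_single_step_forward_equals_backward_direction(self, rng):
        # with l = 1 both directions see the same single input
        rng0 = np.random.default_rng(1)
        layer = BiLSTM(d_in=3, units=4, rng=rng0)
        # copy forward weights into backward LSTM so halves must agree
        layer.bwd.wx.value = layer.fwd.wx.value.copy()
        layer.bwd.wh.value = layer.fwd.wh.value.copy()
        layer.bwd.b.value = layer.fwd.b.value.copy()
        out = layer.forward(rng.normal(size=(2, 1, 3)).astype(np.float32))
        np.testing.assert_allclose(out[:, 0, :4], out[:, 0, 4:], atol=1e-6)

    def test_reversal_symmetry(self, rng):
        layer = BiLSTM(d_in=3, units=4, rng=np.random.default_rng(2))
        layer.bwd.wx.value = layer.fwd.wx.value.copy()
        layer.bwd.wh.value = layer.fwd.wh.value.copy()
        layer.bwd.b.value = layer.fwd.b.value.copy()
        x = rng.normal(size=(1, 5, 3)).astype(np.float32)
        out = layer.forward(x)
        out_rev = layer.forward(x[:, ::-1, :].copy())
        # reversing input swaps forward/backward halves at mirrored steps
        np.testing.assert_allclose(out_rev[0, ::-1, 4:], out[0, :, :4], atol=1e-5)
        np.testing.assert_allclose(out_rev[0, ::-1, :4], out[0, :, 4:], atol=1e-5)

    def test_empty_sequence_raises(self):
        layer = BiLSTM(d_in=3, units=4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer.forward(np.zeros((1, 0, 3), dtype=np.float32))


class TestAttentionPool:
    def test_identical_steps_give_uniform_weights(self, rng):
        h = np.tile(rng.normal(size=(1, 3)), (4, 1))
        out = attention_pool(h, rng.normal(size=3), 0.1)
        np.testing.assert_allclose(out.weights, np.full(4, 0.25), atol=1e-12)
        np.testing.assert_allclose(out.pooled, h[0], atol=1e-12)

    def test_single_step(self, rng):
        h = rng.normal(size=(1, 3))
        out = attention_pool(h, rng.normal(size=3), -0.4)
        assert out.weights.shape == (1,)
        np.testing.assert_allclose(out.weights, [1.0])
        np.testing.assert_allclose(out.pooled, h[0])

    def test_matches_direct_recomputation(self, rng):
        h = rng.normal(size=(4, 3))
        w = rng.normal(size=3)
        b = float(rng.normal())
        out = attention_pool(h, w, b)
        scores = elu(h @ w + b)
        a = np.exp(scores) / np.exp(scores).sum()
        np.testing.assert_allclose(out.weights, a, atol=1e-6)
        np.testing.assert_allclose(out.pooled, a @ h, atol=1e-6)

    def test_weights_simplex_and_shift_invariance(self, rng):
        net = AttentionNetwork(NetConfig(), (16, 16, 1), seed=9)
        x = rng.random((3, 5, 16, 16, 1)).astype(np.float32)
        net.forward(x)
        a = net.last_attention
        assert np.all(a >= 0)
        np.testing.assert_allclose(a.sum(axis=1), np.ones(3), atol=1e-6)
        # shifting all pre-softmax scores leaves the weights unchanged
        h = rng.normal(size=(2, 4))
        scores = h @ np.ones(4)
        np.testing.assert_allclose(softmax(scores), softmax(scores + 10.0),
                                   atol=1e-6)

    def test_pooled_lies_in_convex_hull(self, rng):
        h = rng.normal(size=(6, 4))
        out = attention_pool(h, rng.normal(size=4), 0.0)
        assert np.all(out.pooled <= h.max(axis=0) + 1e-9)
        assert np.all(out.pooled >= h.min(axis=0) - 1e-9)


class TestClassifier:
    def test_probabilities_normalised_and_deterministic(self, rng):
        net = AttentionNetwork(NetConfig(n_classes=2), (16, 16, 1), seed=4)
        x = rng.random((3, 2, 16, 16, 1)).astype(np.float32)
        p1 = net.predict_proba(x)
        p2 = net.predict_proba(x)
        assert p1.shape == (3, 2)
        assert np.all(p1 >= 0)
        np.testing.assert_allclose(p1.sum(axis=1), np.ones(3), atol=1e-6)
        np.testing.assert_array_equal(p1, p2)  # inference has no dropout

    def test_dropout_only_active_in_training(self, rng):
        net = AttentionNetwork(NetConfig(), (16, 16, 1), seed=4)
        x = rng.random((2, 2, 16, 16, 1)).astype(np.float32)
        z_train_a = net.forward(x, train=True)
        z_train_b = net.forward(x, train=True)
        assert not np.allclose(z_train_a, z_train_b)  # dropout masks differ
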