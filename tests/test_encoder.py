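"""Causal-attention encoder: positional encoding, causality, attention, CrossNorm."""

import numpy as np
import pytest

from somnostage.autodiff import Tensor, causal_conv1d, softmax
from somnostage.nn.core import LayerNorm
from somnostage.nn.encoder import (
    CausalConv1d,
    EncoderConfig,
    EncoderLayer,
    EncoderStack,
    MultiHeadAttention,
    PositionalEncoding,
    crossnorm,
    sinusoid_table,
)


def small_cfg(**kw):
    defaults = dict(model_dim=8, n_layers=1, n_heads=2, ffn_hidden=12, dropout=0.0)
    defaults.update(kw)
    return EncoderConfig(**defaults)


class TestPositionalEncoding:
    def test_zero_input_yields_the_table(self):
        pe = PositionalEncoding(8)
        out = pe(Tensor(np.zeros((1, 5, 8))))
        np.testing.assert_allclose(out.data[0], sinusoid_table(5, 8))

    def test_double_application_differs_from_single(self, rng):
        pe = PositionalEncoding(8)
        x = Tensor(rng.normal(size=(1, 5, 8)))
        once, twice = pe(x), pe(pe(x))
        assert not np.allclose(once.data, twice.data)

    def test_positions_receive_distinct_encodings(self):
        table = sinusoid_table(29, 2)
        assert len({tuple(row) for row in np.round(table, 12)}) == 29


class TestCausalConv:
    def test_identity_kernel_reproduces_input(self, rng):
        conv = CausalConv1d(4, 4, kernel=3, rng=rng).set_identity()
        x = Tensor(rng.normal(size=(2, 6, 4)))
        np.testing.assert_allclose(conv(x).data, x.data, atol=1e-12)

    def test_hand_convolution_with_left_padding(self):
        # input [1,2,3,4] with an all-ones width-3 kernel and 2 left zeros
        x = Tensor(np.array([[[1.0], [2.0], [3.0], [4.0]]]))
        w = Tensor(np.ones((3, 1, 1)))
        out = causal_conv1d(x, w)
        np.testing.assert_allclose(out.data[0, :, 0], [1.0, 3.0, 6.0, 9.0])

    def test_future_perturbations_cannot_reach_the_past(self, rng):
        conv = CausalConv1d(3, 5, kernel=3, rng=rng)
        x = rng.normal(size=(1, 20, 3))
        base = conv(Tensor(x)).data
        perturbed = x.copy()
        perturbed[:, 10:, :] += rng.normal(size=(1, 10, 3))
        out = conv(Tensor(perturbed)).data
        np.testing.assert_array_equal(base[:, :10], out[:, :10])
        assert not np.allclose(base[:, 10:], out[:, 10:])


class TestMultiHeadAttention:
    def test_zero_query_key_projections_average_the_values(self, rng):
        cfg = small_cfg()
        mha = MultiHeadAttention(cfg, rng)
        for proj in (mha.proj_q, mha.proj_k):
            proj.weight.data[:] = 0.0
            proj.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 6, 8)))
        out = mha(x)
        v_hat = mha.proj_v(x).data
        np.testing.assert_allclose(mha.last_attention, 1.0 / 6, atol=1e-12)
        expected = np.repeat(v_hat.mean(axis=1, keepdims=True), 6, axis=1)
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_matches_brute_force_single_head_attention(self, rng):
        cfg = EncoderConfig(model_dim=2, n_layers=1, n_heads=1, causal_qkv=False)
        mha = MultiHeadAttention(cfg, rng)
        wq = np.array([[0.5, -1.0], [2.0, 0.25]])
        wk = np.array([[1.0, 0.0], [0.0, -0.5]])
        wv = np.array([[0.75, 1.5], [-0.25, 1.0]])
        for proj, w in [(mha.proj_q, wq), (mha.proj_k, wk), (mha.proj_v, wv)]:
            proj.weight.data = w.copy()
            proj.bias.data[:] = 0.0
        x = np.array([[[1.0, 2.0], [3.0, -1.0]]])
        out = mha(Tensor(x)).data
        # independent brute-force oracle
        q, k, v = x[0] @ wq, x[0] @ wk, x[0] @ wv
        scores = q @ k.T / np.sqrt(2.0)
        weights = np.exp(scores - scores.max(axis=1, keepdims=True))
        weights /= weights.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out[0], weights @ v, atol=1e-6)

    def test_head_partitioning_restores_model_dim(self, rng):
        cfg = EncoderConfig(model_dim=128, n_layers=1, n_heads=8)
        mha = MultiHeadAttention(cfg, rng)
        assert mha.head_dim == 16
        out = mha(Tensor(rng.normal(size=(2, 29, 128))))
        assert out.shape == (2, 29, 128)

    def test_attention_rows_are_probability_vectors(self, rng):
        mha = MultiHeadAttention(small_cfg(), rng)
        mha(Tensor(rng.normal(size=(3, 7, 8))))
        assert (mha.last_attention >= 0).all()
        np.testing.assert_allclose(mha.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_heads_must_divide_model_dim(self):
        with pytest.raises(ValueError, match="divide"):
            EncoderConfig(model_dim=10, n_layers=1, n_heads=4)


class TestCrossNorm:
    def test_moment_exchange(self, rng):
        a = rng.normal(size=(30, 6))
        a = (a - a.mean(axis=0)) / a.std(axis=0)  # per-feature mean 0, std 1
        b = rng.normal(size=(30, 6))
        b = (b - b.mean(axis=0)) / b.std(axis=0) * 2.0 + 5.0  # mean 5, std 2
        a2, b2 = crossnorm(a, b)
        np.testing.assert_allclose(a2.mean(axis=0), 5.0, atol=1e-5)
        np.testing.assert_allclose(a2.std(axis=0), 2.0, atol=1e-5)
        np.testing.assert_allclose(b2.mean(axis=0), 0.0, atol=1e-5)
        np.testing.assert_allclose(b2.std(axis=0), 1.0, atol=1e-5)

    def test_self_exchange_is_identity(self, rng):
        a = rng.normal(size=(10, 4))
        a2, b2 = crossnorm(a, a)
        np.testing.assert_allclose(a2, a, atol=1e-6)
        np.testing.assert_allclose(b2, a, atol=1e-6)

    def test_double_exchange_recovers_originals(self, rng):
        a, b = rng.normal(size=(12, 5)), 3.0 * rng.normal(size=(12, 5)) + 1.0
        a2, b2 = crossnorm(a, b)
        a3, b3 = crossnorm(a2, b2)
        np.testing.assert_allclose(a3, a, atol=1e-5)
        np.testing.assert_allclose(b3, b, atol=1e-5)

    def test_pooled_moments_conserved(self, rng):
        a, b = rng.normal(size=(20, 4)), 2.0 * rng.normal(size=(20, 4)) - 1.0
        a2, b2 = crossnorm(a, b)
        pooled = np.concatenate([a, b])
        pooled2 = np.concatenate([a2, b2])
        np.testing.assert_allclose(pooled.mean(axis=0), pooled2.mean(axis=0), atol=1e-4)
        np.testing.assert_allclose(pooled.std(axis=0), pooled2.std(axis=0), atol=1e-3)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            crossnorm(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestEncoderLayer:
    def test_eval_forward_is_deterministic(self, rng):
        layer = EncoderLayer(small_cfg(dropout=0.1), rng).eval()
        x = rng.normal(size=(2, 7, 8))
        np.testing.assert_array_equal(layer(Tensor(x)).data, layer(Tensor(x)).data)

    def test_shape_preserved(self, rng):
        layer = EncoderLayer(small_cfg(), rng).eval()
        out = layer(Tensor(rng.normal(size=(3, 11, 8))))
        assert out.shape == (3, 11, 8)

    def test_zeroed_sublayers_reduce_to_double_layernorm(self, rng):
        layer = EncoderLayer(small_cfg(), rng).eval()
        for proj in (layer.mha.proj_q, layer.mha.proj_k, layer.mha.proj_v):
            proj.weight.data[:] = 0.0
            proj.bias.data[:] = 0.0
        for lin in (layer.ffn_in, layer.ffn_out):
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0
        # MHA of zero V is zero, FFN is zero: residual path is x -> LN -> LN
        x = Tensor(rng.normal(size=(1, 5, 8)))
        ln = LayerNorm(8)
        np.testing.assert_allclose(layer(x).data, ln(ln(x)).data, atol=1e-10)

    def test_training_crossnorm_draws_from_installed_rng(self, rng):
        layer = EncoderLayer(small_cfg(crossnorm_mode="train_only_exchange"), rng).train()
        layer.apply_rng(np.random.default_rng(3))
        x = rng.normal(size=(4, 6, 8))
        out1 = layer(Tensor(x)).data
        layer.apply_rng(np.random.default_rng(3))
        out2 = layer(Tensor(x)).data
        np.testing.assert_array_equal(out1, out2)


class TestEncoderStack:
    def test_single_layer_stack_equals_layer(self, rng):
        cfg = small_cfg()
        stack = EncoderStack(cfg, np.random.default_rng(5)).eval()
        layer = EncoderLayer(cfg, np.random.default_rng(5)).eval()
        x = rng.normal(size=(2, 6, 8))
        np.testing.assert_allclose(stack(Tensor(x)).data, layer(Tensor(x)).data, atol=1e-12)

    def test_full_depth_preserves_image_shape(self, rng):
        cfg = EncoderConfig(model_dim=128, n_layers=8)
        stack = EncoderStack(cfg, rng).eval()
        out = stack(Tensor(rng.normal(size=(1, 29, 128))))
        assert out.shape == (1, 29, 128)

    def test_parameter_count_grows_with_depth(self):
        counts = [
            EncoderStack(small_cfg(n_layers=n), np.random.default_rng(0)).n_parameters()
            for n in (1, 2, 3)
        ]
        assert counts[0] < counts[1] < counts[2]
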