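"""Assembled network: branches, fusion, classification head, ablations."""

import numpy as np
import pytest

from somnostage.autodiff import Tensor
from somnostage.model import ModelConfig, SleepStageNet
from somnostage.stages import StageLabel


@pytest.fixture(scope="module")
def reduced_model():
    return SleepStageNet(ModelConfig.reduced(), seed=0).eval()


@pytest.fixture(scope="module")
def images():
    return np.random.default_rng(1).normal(size=(4, 3, 29, 128))


class TestChannelBranch:
    def test_branch_preserves_token_count(self, reduced_model, images):
        out = reduced_model.channel_branch(Tensor(images[:, 0]), 0)
        assert out.shape == (4, 29, 32)

    def test_full_size_branch_keeps_29_by_128(self):
        model = SleepStageNet(ModelConfig(), seed=0).eval()
        x = np.random.default_rng(0).normal(size=(1, 29, 128))
        assert model.channel_branch(Tensor(x), 0).shape == (1, 29, 128)

    def test_eval_branch_deterministic(self, reduced_model, images):
        a = reduced_model.channel_branch(Tensor(images[:, 1]), 1).data
        b = reduced_model.channel_branch(Tensor(images[:, 1]), 1).data
        np.testing.assert_array_equal(a, b)


class TestFuseChannels:
    def test_concatenation_shape(self, reduced_model, images):
        branches = [Tensor(np.random.default_rng(i).normal(size=(2, 29, 32))) for i in range(3)]
        assert reduced_model.fuse_channels(branches).shape == (2, 29, 96)

    def test_wrong_channel_count_rejected(self, reduced_model):
        with pytest.raises(ValueError, match="3 channel"):
            reduced_model.fuse_channels([Tensor(np.zeros((1, 29, 32)))] * 2)

    def test_eval_rows_are_layer_normalized(self, reduced_model):
        branches = [Tensor(np.random.default_rng(i).normal(size=(2, 29, 32))) for i in range(3)]
        out = reduced_model.fuse_channels(branches).data
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-5)
        np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-3)


class TestClassify:
    def test_probabilities_sum_to_one_over_random_draws(self, reduced_model):
        rng = np.random.default_rng(2)
        probs = reduced_model.predict_proba(rng.normal(size=(16, 3, 29, 128)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_zero_head_gives_uniform_probabilities(self):
        model = SleepStageNet(ModelConfig.reduced(), seed=0).eval()
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        probs = model.predict_proba(np.random.default_rng(0).normal(size=(3, 3, 29, 128)))
        np.testing.assert_allclose(probs, 0.2, atol=1e-12)

    def test_argmax_ties_break_toward_lowest_stage(self):
        model = SleepStageNet(ModelConfig.reduced(), seed=0).eval()
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0  # all logits equal -> tie across all stages
        preds = model.predict(np.random.default_rng(0).normal(size=(2, 3, 29, 128)))
        assert all(p.predicted == StageLabel.W for p in preds)


class TestForward:
    def test_batch_yields_one_prediction_each(self, reduced_model, images):
        preds = reduced_model.predict(images)
        assert len(preds) == 4
        for p in preds:
            assert p.probabilities.shape == (5,)
            assert np.isclose(p.probabilities.sum(), 1.0, atol=1e-6)

    def test_duplicated_batch_element_predicts_identically(self, reduced_model, images):
        single = reduced_model.predict_proba(images[:1])
        doubled = reduced_model.predict_proba(np.concatenate([images[:1], images[:1]]))
        np.testing.assert_array_equal(doubled[0], doubled[1])
        # across different batch shapes BLAS summation order may differ by ulps
        np.testing.assert_allclose(single[0], doubled[0], atol=1e-12)

    def test_batch_composition_does_not_change_predictions(self, reduced_model, images):
        full = reduced_model.predict_proba(images)
        subset = reduced_model.predict_proba(images[1:3])
        np.testing.assert_allclose(full[1:3], subset, atol=1e-12)

    def test_wrong_input_shape_rejected(self, reduced_model):
        with pytest.raises(ValueError, match="batch"):
            reduced_model(np.zeros((2, 29, 128)))


class TestBuildAndAblation:
    def test_same_config_same_parameter_count_and_weights(self):
        a = SleepStageNet(ModelConfig.reduced(), seed=3)
        b = SleepStageNet(ModelConfig.reduced(), seed=3)
        assert a.n_parameters() == b.n_parameters()
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_ablation_parameter_lattice(self):
        def count(use_ccte, use_mfem):
            cfg = ModelConfig.reduced()
            cfg.use_ccte, cfg.use_mfem = use_ccte, use_mfem
            return SleepStageNet(cfg, seed=0).n_parameters()

        bl = count(False, False)
        bl_mfem = count(False, True)
        bl_ccte = count(True, False)
        full = count(True, True)
        assert bl < bl_mfem < full
        assert bl < bl_ccte <= full

    def test_fused_dim_mismatch_rejected(self):
        from somnostage.nn.encoder import EncoderConfig

        with pytest.raises(ValueError, match="fused model_dim"):
            ModelConfig(
                encoder_single=EncoderConfig(model_dim=32, n_layers=1),
                encoder_fused=EncoderConfig(model_dim=128, n_layers=1),
            )

    def test_state_dict_round_trip(self, reduced_model, images):
        state = reduced_model.state_dict()
        clone = SleepStageNet(ModelConfig.reduced(), seed=99)
        clone.load_state_dict(state)
        np.testing.assert_array_equal(
            clone.eval().predict_proba(images), reduced_model.predict_proba(images)
        )
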