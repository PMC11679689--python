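"""Multi-task composition: taps, heads, grade decoding, encoder transfer."""

import numpy as np
import pytest

from drumtl.data_io import GradeCodec
from drumtl.multitask import (
    REGRESSOR,
    ClassHeadConfig,
    MultiTaskModel,
    MultiTaskOutputs,
    multiscale_feature_vector,
    predict_grade,
    transfer_encoder_parameters,
    trunk_parameter_names,
    write_predictions,
)
from drumtl.networks import AttentionUNet, BackboneConfig, BackboneOutputs
from drumtl.nn.tensor import Tensor


def _fake_backbone_outputs(rng, c_enc=4, c_bridge=8):
    enc = Tensor(rng.standard_normal((2, c_enc, 4, 4)))
    bridge = Tensor(rng.standard_normal((2, c_bridge, 2, 2)))
    dec = Tensor(rng.standard_normal((2, c_enc, 4, 4)))
    dummy = Tensor(np.zeros((2, 1, 8, 8)))
    return BackboneOutputs([enc], bridge, [dec], dummy, dummy)


class TestMultiscaleFeatures:
    def test_vector_length_is_sum_of_tapped_channels(self):
        model = MultiTaskModel(BackboneConfig(levels=5, base_channels=32, side=64), seed=0)
        out = model.backbone(np.zeros((1, 1, 64, 64), np.float32))
        vec = multiscale_feature_vector(out, model.head_config)
        assert vec.shape == (1, 256 + 512 + 256)

    def test_constant_map_gap_is_exact(self, rng):
        outs = _fake_backbone_outputs(rng)
        outs.bridge_feature = Tensor(np.full((2, 8, 2, 2), 3.25))
        vec = multiscale_feature_vector(outs, ClassHeadConfig())
        assert np.allclose(vec.data[:, 4:12], 3.25)

    def test_spatial_permutation_invariance(self, rng):
        outs = _fake_backbone_outputs(rng)
        vec_a = multiscale_feature_vector(outs, ClassHeadConfig()).data
        flat = outs.encoder_features[0].data.reshape(2, 4, -1)
        perm = rng.permutation(16)
        outs.encoder_features[0] = Tensor(flat[:, :, perm].reshape(2, 4, 4, 4))
        vec_b = multiscale_feature_vector(outs, ClassHeadConfig()).data
        assert np.allclose(vec_a, vec_b)

    def test_missing_tap_rejected(self, rng):
        outs = _fake_backbone_outputs(rng)
        outs.decoder_features = []
        with pytest.raises(ValueError):
            multiscale_feature_vector(outs, ClassHeadConfig())


class TestForward:
    def test_softmax_head_contract(self, rng, tiny_backbone_config):
        model = MultiTaskModel(tiny_backbone_config, seed=0)
        model.eval()
        x = rng.random((3, 1, 16, 16))
        out = model(x)
        assert out.class_prob.shape == (3, 7)
        assert np.allclose(out.class_prob.data.sum(axis=1), 1.0, atol=1e-6)
        assert out.seg_prob.shape == (3, 1, 16, 16)

    def test_regression_head_nonnegative(self, rng, tiny_backbone_config):
        model = MultiTaskModel(
            tiny_backbone_config, ClassHeadConfig(head_kind=REGRESSOR), seed=0
        )
        model.eval()
        out = model(rng.random((4, 1, 16, 16)))
        assert out.stage_value.shape == (4,)
        assert np.all(out.stage_value.data >= 0)
        assert out.class_prob is None

    def test_encoder_runs_once_per_forward(self, rng, tiny_backbone_config, monkeypatch):
        model = MultiTaskModel(tiny_backbone_config, seed=0)
        calls = {"n": 0}
        orig = AttentionUNet.encode

        def counting(self, x):
            calls["n"] += 1
            return orig(self, x)

        monkeypatch.setattr(AttentionUNet, "encode", counting)
        model(rng.random((2, 1, 16, 16)))
        assert calls["n"] == 1

    def test_deterministic_without_dropout(self, rng, tiny_backbone_config):
        model = MultiTaskModel(
            tiny_backbone_config, ClassHeadConfig(dropout_rate=0.0), seed=0
        )
        x = rng.random((2, 1, 16, 16))
        a = model(x).class_prob.data
        b = model(x).class_prob.data
        assert np.array_equal(a, b)


class TestPredictGrade:
    def test_one_hot_argmax_decoded(self):
        probs = np.zeros((1, 7))
        probs[0, 2] = 1.0
        out = MultiTaskOutputs(seg_prob=None, class_prob=Tensor(probs))
        assert predict_grade(out, GradeCodec.for_bone("radius")) == ["R7"]

    def test_argmax_tie_breaks_low(self):
        probs = np.full((1, 7), 1 / 7)
        out = MultiTaskOutputs(seg_prob=None, class_prob=Tensor(probs))
        assert predict_grade(out, GradeCodec.for_bone("radius")) == ["R5"]

    @pytest.mark.parametrize(
        "value,label", [(6.7, "R11"), (0.49, "R5"), (3.5, "R9"), (9.0, "R11")]
    )
    def test_regression_round_and_clip(self, value, label):
        out = MultiTaskOutputs(seg_prob=None, stage_value=Tensor(np.array([value])))
        assert predict_grade(out, GradeCodec.for_bone("radius")) == [label]

    def test_no_head_output_rejected(self):
        with pytest.raises(ValueError):
            predict_grade(MultiTaskOutputs(seg_prob=None), GradeCodec.for_bone("ulna"))


class TestTransfer:
    def _pair(self, tiny_backbone_config):
        src = AttentionUNet(tiny_backbone_config, seed=11)
        dst = MultiTaskModel(tiny_backbone_config, seed=22)
        return src, dst

    def test_trunk_bit_equal_after_transfer(self, tiny_backbone_config):
        src, dst = self._pair(tiny_backbone_config)
        _, names = transfer_encoder_parameters(src, dst)
        src_state = src.state_dict()
        dst_params = dict(dst.backbone.named_parameters())
        assert names
        for name in trunk_parameter_names(dst):
            assert np.array_equal(dst_params[name].data, src_state[name])

    def test_head_and_decoder_keep_fresh_init(self, tiny_backbone_config):
        src, dst = self._pair(tiny_backbone_config)
        before = {n: p.data.copy() for n, p in dst.named_parameters()}
        transfer_encoder_parameters(src, dst)
        trunk = {f"backbone.{n}" for n in trunk_parameter_names(dst)}
        for name, p in dst.named_parameters():
            if name not in trunk:
                assert np.array_equal(p.data, before[name]), name

    def test_transfer_is_idempotent(self, tiny_backbone_config):
        src, dst = self._pair(tiny_backbone_config)
        transfer_encoder_parameters(src, dst)
        snap = {n: p.data.copy() for n, p in dst.named_parameters()}
        transfer_encoder_parameters(src, dst)
        for name, p in dst.named_parameters():
            assert np.array_equal(p.data, snap[name])

    def test_config_mismatch_refused_with_diff(self, tiny_backbone_config):
        src = AttentionUNet(BackboneConfig(levels=4, base_channels=4, side=16), seed=0)
        dst = MultiTaskModel(tiny_backbone_config, seed=0)
        with pytest.raises(ValueError, match="levels"):
            transfer_encoder_parameters(src, dst)

    def test_encoder_only_scope_leaves_bridge(self, tiny_backbone_config):
        src, dst = self._pair(tiny_backbone_config)
        before = {n: p.data.copy() for n, p in dst.backbone.named_parameters()}
        _, names = transfer_encoder_parameters(src, dst, include_bridge=False)
        assert all(n.startswith("encoder_blocks.") for n in names)
        for n, p in dst.backbone.named_parameters():
            if n.startswith("bridge."):
                assert np.array_equal(p.data, before[n])


def test_prediction_csv_formats(tmp_path, rng):
    codec = GradeCodec.for_bone("ulna")
    probs = rng.random((2, 7))
    probs /= probs.sum(axis=1, keepdims=True)
    out = MultiTaskOutputs(seg_prob=None, class_prob=Tensor(probs))
    write_predictions(tmp_path / "p.csv", ["a", "b"], out, codec)
    header = (tmp_path / "p.csv").read_text().splitlines()[0]
    assert header == "sample_id,predicted_grade," + ",".join(f"prob_{j}" for j in range(7))
    reg = MultiTaskOutputs(seg_prob=None, stage_value=Tensor(np.array([1.2, 5.9])))
    write_predictions(tmp_path / "r.csv", ["a", "b"], reg, codec)
    lines = (tmp_path / "r.csv").read_text().splitlines()
    assert lines[0] == "sample_id,predicted_grade,raw_value"
    assert lines[2].startswith("b,U9,")
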