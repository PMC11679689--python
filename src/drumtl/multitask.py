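"""Shared-encoder multi-task model: segmentation branch + grading head.

One backbone pass feeds both branches.  The segmentation branch is the
attention U-Net decoder; the grading branch taps three multi-scale feature
maps — the last encoder block, the bridge, and the first decoder block —
reduces each to a per-channel vector by global average pooling (GAP),
concatenates them, and classifies through two ReLU dense layers (256 and
128 units, with dropout) into either a 7-way softmax over maturity stages
or, for the regression variant, a single ReLU unit whose rounded output is
the stage index.  Radius and ulna are graded by two separate model
instances with identical architecture.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .data_io import GradeCodec
from .networks import AttentionUNet, BackboneConfig, BackboneOutputs
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "ClassHeadConfig",
    "MultiTaskOutputs",
    "MultiTaskModel",
    "multiscale_feature_vector",
    "predict_grade",
    "transfer_encoder_parameters",
    "write_predictions",
]

SOFTMAX = "softmax_classifier"
REGRESSOR = "relu_regressor"


@dataclass(frozen=True)
class ClassHeadConfig:
    dense_units: tuple[int, int] = (256, 128)
    dropout_rate: float = 0.3
    n_classes: int = 7
    head_kind: str = SOFTMAX

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.head_kind not in (SOFTMAX, REGRESSOR):
            raise ValueError(f"unknown head_kind {self.head_kind!r}")


@dataclass
class MultiTaskOutputs:
    seg_prob: Tensor
    class_prob: Tensor | None = None  # (N, 7), rows sum to 1
    stage_value: Tensor | None = None  # (N,), nonnegative
    class_logits: Tensor | None = None
    backbone: BackboneOutputs | None = None


def multiscale_feature_vector(outputs: BackboneOutputs, cfg: ClassHeadConfig) -> Tensor:
    """GAP each tapped feature map and concatenate (encoder-last, bridge,
    decoder-first order); result is (N, sum of tapped channel widths)."""
    if not outputs.encoder_features or not outputs.decoder_features:
        raise ValueError("backbone outputs are missing tap-point features")
    taps = (
        outputs.encoder_features[-1],
        outputs.bridge_feature,
        outputs.decoder_features[0],
    )
    return concat([F.global_avg_pool(t) for t in taps], axis=1)


def _softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    e = (logits - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


class MultiTaskModel(nn.Module):
    """Attention U-Net backbone plus the GAP multi-scale grading head."""

    def __init__(
        self,
        backbone_config: BackboneConfig,
        head_config: ClassHeadConfig = ClassHeadConfig(),
        seed: int = 0,
    ):
        super().__init__()
        self.head_config = head_config
        self.backbone = AttentionUNet(backbone_config, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
        dt = backbone_config.np_dtype
        n_enc = backbone_config.levels - 1
        feat_dim = (
            backbone_config.channels(n_enc - 1)
            + backbone_config.channels(n_enc)
            + backbone_config.channels(n_enc - 1)
        )
        u1, u2 = head_config.dense_units
        self.fc1 = nn.Linear(feat_dim, u1, rng, dtype=dt)
        self.fc2 = nn.Linear(u1, u2, rng, dtype=dt)
        out_units = head_config.n_classes if head_config.head_kind == SOFTMAX else 1
        self.fc_out = nn.Linear(u2, out_units, rng, dtype=dt)
        drop_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]).generate_state(1)[0])
        self.drop1 = nn.Dropout(head_config.dropout_rate, drop_rng)
        self.drop2 = nn.Dropout(head_config.dropout_rate, drop_rng)

    @property
    def backbone_config(self) -> BackboneConfig:
        return self.backbone.config

    def forward(self, x) -> MultiTaskOutputs:
        bb = self.backbone(x)  # single encoder pass feeds both branches
        feat = multiscale_feature_vector(bb, self.head_config)
        h = self.drop1(self.fc1(feat).relu())
        h = self.drop2(self.fc2(h).relu())
        logits = self.fc_out(h)
        out = MultiTaskOutputs(seg_prob=bb.seg_prob, class_logits=logits, backbone=bb)
        if self.head_config.head_kind == SOFTMAX:
            out.class_prob = _softmax(logits)
        else:
            out.stage_value = logits.relu().reshape(logits.shape[0])
        return out


def predict_grade(
    outputs: MultiTaskOutputs, codec: GradeCodec
) -> list[str]:
    """Decode head outputs into grade labels.

    Softmax head: argmax stage (ties break to the lowest index).  Regression
    head: round half-up and clip to the valid stage range.
    """
    if outputs.class_prob is not None:
        idx = outputs.class_prob.data.argmax(axis=1)
    elif outputs.stage_value is not None:
        idx = np.clip(np.floor(outputs.stage_value.data + 0.5), 0, 6).astype(int)
    else:
        raise ValueError("outputs carry neither class probabilities nor stage values")
    return [codec.decode(int(i)) for i in idx]


def _trunk_prefixes(include_bridge: bool) -> tuple[str, ...]:
    return ("encoder_blocks.", "bridge.") if include_bridge else ("encoder_blocks.",)


def transfer_encoder_parameters(
    pretrained_backbone: AttentionUNet,
    multitask_model: MultiTaskModel,
    include_bridge: bool = True,
) -> tuple[MultiTaskModel, list[str]]:
    """Copy shared-trunk parameters from a pretrained backbone.

    Every encoder (and, by default, bridge) parameter and buffer of the
    multi-task model is overwritten bit-exactly with the pretrained value;
    all other parameters keep their fresh initialisation.  Returns the
    model and the list of transferred tensor names.  Refuses on
    architecture mismatch with a field-by-field diff.
    """
    src_cfg, dst_cfg = pretrained_backbone.config, multitask_model.backbone_config
    diffs = [
        f"{k}: pretrained={v!r} target={getattr(dst_cfg, k)!r}"
        for k, v in vars(src_cfg).items()
        if getattr(dst_cfg, k) != v and k != "side"
    ]
    if diffs:
        raise ValueError("backbone config mismatch; " + "; ".join(diffs))
    prefixes = _trunk_prefixes(include_bridge)
    src_state = pretrained_backbone.state_dict()
    transferred: list[str] = []
    dst_params = dict(multitask_model.backbone.named_parameters())
    dst_bufs = dict(multitask_model.backbone.named_buffers())
    for name, value in src_state.items():
        if not name.startswith(prefixes):
            continue
        if name in dst_params:
            dst_params[name].data = value.copy()
        elif name in dst_bufs:
            dst_bufs[name][...] = value
        else:  # pragma: no cover - guarded by config check
            raise ValueError(f"pretrained tensor {name} absent from target model")
        transferred.append(name)
    return multitask_model, transferred


def trunk_parameter_names(model: MultiTaskModel, include_bridge: bool = True) -> list[str]:
    """Names of the shared-trunk parameters within the multi-task backbone."""
    prefixes = _trunk_prefixes(include_bridge)
    return [
        n for n, _ in model.backbone.named_parameters() if n.startswith(prefixes)
    ]


def write_predictions(
    path: str | Path,
    sample_ids: list[str],
    outputs: MultiTaskOutputs,
    codec: GradeCodec,
) -> None:
    """Prediction CSV: probabilities for the softmax head, raw value for the
    regression head."""
    grades = predict_grade(outputs, codec)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if outputs.class_prob is not None:
            writer.writerow(
                ["sample_id", "predicted_grade"] + [f"prob_{j}" for j in range(7)]
            )
            for sid, grade, probs in zip(sample_ids, grades, outputs.class_prob.data):
                writer.writerow([sid, grade] + [f"{p:.6f}" for p in probs])
        else:
            writer.writerow(["sample_id", "predicted_grade", "raw_value"])
            for sid, grade, val in zip(sample_ids, grades, outputs.stage_value.data):
                writer.writerow([sid, grade, f"{val:.6f}"])
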