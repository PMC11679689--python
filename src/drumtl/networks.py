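"""Attention-gated U-Net backbone for distal radius/ulna segmentation.

The backbone is a five-level encoder/bridge/decoder: four encoder blocks
(two 3x3 convolutions + optional batch norm + ReLU each) with 2x2 max
pooling, a bottleneck ("bridge") block, and a symmetric decoder that
upsamples bilinearly and refines with convolution blocks.  Each skip
connection can pass through an additive attention gate before
concatenation: a coarser gating signal g and the skip feature x are
projected to an intermediate width by 1x1 convolutions, summed, rectified,
and squeezed to a single-channel response q whose sigmoid is the spatial
attention coefficient map alpha in (0,1); the skip feature is multiplied
by alpha elementwise.  With ``use_attention=False`` the same architecture
degenerates to a conventional U-Net (the ablation backbone), sharing every
non-gate parameter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = [
    "BackboneConfig",
    "BackboneOutputs",
    "AttentionGate",
    "ConvBlock",
    "AttentionUNet",
    "attention_gate",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

CHECKPOINT_VERSION = "drumtl-ckpt-1"


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters of the shared backbone.

    ``levels`` counts encoder blocks plus the bridge (5 means 4 encoder
    blocks + bridge); channel width doubles at every level starting from
    ``base_channels``.
    """

    levels: int = 5
    base_channels: int = 32
    use_attention: bool = True
    use_batchnorm: bool = True
    side: int = 256
    dtype: str = "float32"

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type

    def channels(self, level: int) -> int:
        return self.base_channels * 2**level


@dataclass
class BackboneOutputs:
    """Feature tensors produced by one backbone pass."""

    encoder_features: list[Tensor]
    bridge_feature: Tensor
    decoder_features: list[Tensor]  # deepest (first decoder block) first
    seg_logits: Tensor
    seg_prob: Tensor


class ConvBlock(nn.Module):
    """Two 3x3 convolutions, each followed by optional batch norm and ReLU."""

    def __init__(self, c_in: int, c_out: int, rng, use_batchnorm: bool, dtype):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, dtype=dtype)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(c_out, dtype=dtype) if use_batchnorm else None
        self.bn2 = nn.BatchNorm2d(c_out, dtype=dtype) if use_batchnorm else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv1(x)
        if self.bn1 is not None:
            x = self.bn1(x)
        x = x.relu()
        x = self.conv2(x)
        if self.bn2 is not None:
            x = self.bn2(x)
        return x.relu()


class AttentionGate(nn.Module):
    """Additive attention gate.

    The skip feature x (F_l channels, fine resolution) is area-pooled to
    the gating signal's resolution, both are projected to F_int channels by
    1x1 convolutions (the gating projection carries the shared additive
    bias b), summed and rectified; a 1x1 convolution psi with bias b_psi
    produces the pre-activation response q, whose sigmoid is upsampled
    bilinearly back to the skip resolution as the coefficient map alpha.
    """

    def __init__(self, f_l: int, f_g: int, rng, dtype, f_int: int | None = None):
        super().__init__()
        self.f_int = f_int if f_int is not None else max(1, f_l // 2)
        self.theta_x = nn.Conv2d(f_l, self.f_int, 1, rng, bias=False, dtype=dtype)
        self.phi_g = nn.Conv2d(f_g, self.f_int, 1, rng, bias=True, dtype=dtype)
        self.psi = nn.Conv2d(self.f_int, 1, 1, rng, bias=True, dtype=dtype)

    def forward(self, x: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        hx, wx = x.shape[2:]
        hg, wg = g.shape[2:]
        if hg > hx or wg > wx:
            raise ValueError("gating signal must come from a coarser scale")
        x_down = F.avg_pool_to(x, (hg, wg))
        q = self.psi((self.theta_x(x_down) + self.phi_g(g)).relu())
        alpha = F.resize_bilinear(q.sigmoid(), (hx, wx))
        return x * alpha, alpha


def attention_gate(x: Tensor, g: Tensor, gate: AttentionGate) -> tuple[Tensor, Tensor]:
    """Functional wrapper: apply ``gate`` to skip feature ``x`` with gating
    signal ``g``; returns (gated skip, coefficient map alpha)."""
    return gate(x, g)


class AttentionUNet(nn.Module):
    """Encoder/bridge/decoder segmentation backbone with optional gates."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        dt = config.np_dtype
        n_enc = config.levels - 1
        bn = config.use_batchnorm

        self.encoder_blocks = nn.ModuleList()
        c_in = 1
        for l in range(n_enc):
            c_out = config.channels(l)
            self.encoder_blocks.append(ConvBlock(c_in, c_out, rng, bn, dt))
            c_in = c_out
        self.bridge = ConvBlock(c_in, config.channels(n_enc), rng, bn, dt)

        self.up_convs = nn.ModuleList()
        self.gates = nn.ModuleList()
        self.decoder_blocks = nn.ModuleList()
        c_cur = config.channels(n_enc)
        for l in range(n_enc - 1, -1, -1):
            c_skip = config.channels(l)
            self.up_convs.append(nn.Conv2d(c_cur, c_skip, 3, rng, dtype=dt))
            if config.use_attention:
                self.gates.append(AttentionGate(c_skip, c_cur, rng, dt))
            self.decoder_blocks.append(ConvBlock(2 * c_skip, c_skip, rng, bn, dt))
            c_cur = c_skip
        self.out_conv = nn.Conv2d(config.base_channels, 1, 1, rng, dtype=dt)

    # -- forward pieces -------------------------------------------------
    def _check_input(self, x) -> Tensor:
        if isinstance(x, np.ndarray):
            x = Tensor(x.astype(self.config.np_dtype))
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must have shape (N, 1, H, W)")
        div = 2 ** (self.config.levels - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial size {x.shape[2:]} must be divisible by {div} "
                f"for {self.config.levels} levels"
            )
        return x

    def encode(self, x) -> tuple[list[Tensor], Tensor]:
        x = self._check_input(x)
        feats: list[Tensor] = []
        for block in self.encoder_blocks:
            x = block(x)
            feats.append(x)
            x = F.max_pool2d(x, 2)
        return feats, self.bridge(x)

    def decode(self, feats: list[Tensor], bridge: Tensor) -> list[Tensor]:
        cur = bridge
        dec: list[Tensor] = []
        for i, skip in enumerate(reversed(feats)):
            if self.config.use_attention:
                skip, _ = self.gates[i](skip, cur)
            up = self.up_convs[i](F.resize_bilinear(cur, skip.shape[2:])).relu()
            cur = self.decoder_blocks[i](concat([skip, up], axis=1))
            dec.append(cur)
        return dec

    def forward(self, x) -> BackboneOutputs:
        feats, bridge = self.encode(x)
        dec = self.decode(feats, bridge)
        logits = self.out_conv(dec[-1])
        return BackboneOutputs(
            encoder_features=feats,
            bridge_feature=bridge,
            decoder_features=dec,
            seg_logits=logits,
            seg_prob=logits.sigmoid(),
        )

    def predict_mask(self, x, threshold: float = 0.5) -> np.ndarray:
        """Hard segmentation masks (N, H, W) from thresholded probabilities."""
        was_training = self.training
        self.eval()
        try:
            prob = self.forward(x).seg_prob.data[:, 0]
        finally:
            self.train(was_training)
        return (prob > threshold).astype(np.uint8)


# -- checkpointing ------------------------------------------------------


def save_checkpoint(path: str | Path, model: nn.Module, config, extra: dict | None = None) -> None:
    """Persist parameters + buffers with the architecture config embedded."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(config),
        "extra": extra or {},
    }
    np.savez_compressed(path, __meta__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Load a checkpoint; returns (state dict, metadata)."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version in {path}")
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    return state, meta
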