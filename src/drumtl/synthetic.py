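"""Stage-conditional synthetic bone-ROI generator.

Produces grayscale crops of a stylised long-bone end (shaft + epiphysis)
whose boundary morphology encodes a 7-level maturity stage the way the
distal radius/ulna physis does: the radiolucent physis gap between shaft
and epiphysis narrows monotonically with stage, a medial "cap" of the
epiphysis grows over the metaphysis at mid stages, a styloid-like bump
appears at mid stages, and the gap bridges over (fuses) at the final
stages.  The mask is the exact pre-noise foreground, so the stage signal
genuinely lives in the segmented boundary — which is the structural
assumption the multi-task grading model exploits.

This is a test fixture emulating the statistical structure of the task,
not a radiological simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .data_io import GradeCodec, RoiSample, write_image, write_mask

__all__ = [
    "MorphologyParams",
    "SyntheticConfig",
    "stage_morphology",
    "render_sample",
    "generate_dataset",
    "write_dataset",
]

log = logging.getLogger(__name__)

N_STAGES = 7

# per-stage schedules in units of a 64-px canvas (zero-jitter values)
_GAP = np.array([12.0, 10.2, 8.4, 6.6, 4.8, 3.0, 1.2])  # strictly decreasing
_EPI_HEIGHT = np.array([8.0, 8.8, 9.6, 10.4, 11.2, 12.0, 12.8])
_CAPPING = np.array([0.0, 0.0, 0.3, 0.6, 0.85, 1.0, 1.0])
_FUSION = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.5, 1.0])
_STYLOID = np.array([False, False, True, True, True, False, False])


@dataclass(frozen=True)
class MorphologyParams:
    """Geometry of one synthetic bone, in pixels of a 64-px canvas."""

    stage: int
    shaft_width: float
    epiphysis_height: float
    epiphysis_width: float
    physis_gap: float
    capping_extent: float  # 0..1, medial overhang descent across the gap
    fusion_fraction: float  # 0..1, fraction of the gap width bridged
    styloid_bump: bool


@dataclass(frozen=True)
class SyntheticConfig:
    side: int = 64
    n_per_stage: int = 10  # multi-task set
    n_per_stage_pretrain: int = 10
    n_per_stage_test: int = 5
    noise_sd: float = 0.05
    blur_sigma: float = 0.7
    seed: int = 0
    bone: str = "radius"

    def __post_init__(self):
        if self.side % 16:
            raise ValueError("side must be divisible by 16")
        if min(self.n_per_stage, self.n_per_stage_pretrain, self.n_per_stage_test) < 1:
            raise ValueError("per-stage counts must be >= 1")


def stage_morphology(stage: int, jitter_seed: int | None = None) -> MorphologyParams:
    """Deterministic per-stage geometry schedule with bounded jitter.

    With ``jitter_seed=None`` the schedule is exact: the physis gap is
    strictly decreasing in stage and fusion reaches 1 at the last stage.
    """
    if not 0 <= stage < N_STAGES:
        raise ValueError(f"stage must be in [0, {N_STAGES - 1}]")
    if jitter_seed is None:
        j = np.zeros(4)
    else:
        rng = np.random.default_rng(jitter_seed)
        j = rng.uniform(-1.0, 1.0, 4)
    return MorphologyParams(
        stage=stage,
        shaft_width=22.0 + 1.5 * j[0],
        epiphysis_height=float(_EPI_HEIGHT[stage]) + 0.5 * j[1],
        epiphysis_width=27.0 + 0.8 * stage + 1.5 * j[2],
        physis_gap=float(_GAP[stage]) + 0.4 * j[3],
        capping_extent=float(_CAPPING[stage]),
        fusion_fraction=float(_FUSION[stage]),
        styloid_bump=bool(_STYLOID[stage]),
    )


def _draw_mask(p: MorphologyParams, side: int, scale: float = 1.0) -> np.ndarray:
    """Rasterise the foreground geometry; returns a binary (side, side) mask."""
    u = side / 64.0 * scale
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    cx = side / 2.0

    shaft_w = p.shaft_width * u
    gap = p.physis_gap * u
    epi_h = p.epiphysis_height * u
    epi_w = p.epiphysis_width * u

    shaft_top = side - 26.0 * u  # shaft occupies the lower part of the crop
    shaft = (
        (np.abs(xx - cx) <= shaft_w / 2.0)
        & (yy >= shaft_top)
        & (yy <= side - 2.0 * u)
    )

    b = epi_h / 2.0
    a = epi_w / 2.0
    cy = shaft_top - gap - b
    if cy - b < 1.0:
        return np.zeros((side, side), dtype=np.uint8)  # out of bounds sentinel
    epi = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    fg = shaft | epi

    if p.capping_extent > 0:
        # medial lip of the epiphysis descending over the metaphysis corner
        x_med = cx - a
        descent = p.capping_extent * (gap + 3.0 * u)
        cap = (
            (xx >= x_med)
            & (xx <= x_med + 4.0 * u)
            & (yy >= cy)
            & (yy <= cy + b + descent)
        )
        fg |= cap

    if p.fusion_fraction > 0:
        half = p.fusion_fraction * shaft_w / 2.0
        bridge = (
            (np.abs(xx - cx) <= half)
            & (yy >= shaft_top - gap - 1.0 * u)
            & (yy <= shaft_top + 1.0 * u)
        )
        fg |= bridge

    if p.styloid_bump:
        sx, sy = cx + a * 0.75, cy - b * 0.9
        fg |= ((xx - sx) / (3.0 * u)) ** 2 + ((yy - sy) / (4.0 * u)) ** 2 <= 1.0

    return fg.astype(np.uint8)


def render_sample(
    params: MorphologyParams,
    cfg: SyntheticConfig,
    noise_seed: int = 0,
    sample_id: str = "",
) -> RoiSample:
    """Render one crop: bone-like intensities + blur + noise over the mask.

    The mask is the exact pre-noise foreground.  If the geometry leaves the
    canvas, the drawing is retried at a shrunken scale.
    """
    side = cfg.side
    mask = _draw_mask(params, side)
    scale = 1.0
    while mask.sum() == 0 and scale > 0.5:
        scale *= 0.9
        log.warning("geometry out of bounds at stage %d; retrying at scale %.2f",
                    params.stage, scale)
        mask = _draw_mask(params, side, scale)
    if mask.sum() == 0:
        raise RuntimeError("could not fit geometry into the canvas")

    rng = np.random.default_rng(noise_seed)
    img = np.full((side, side), 0.10)
    # bone fill with a brighter cortical rim (near-boundary pixels)
    inside = distance_transform_edt(mask)
    img = np.where(mask > 0, 0.55 + 0.02 * rng.standard_normal((side, side)), img)
    rim = (mask > 0) & (inside <= max(1.5, side / 42.0))
    img[rim] += 0.25
    # mild vertical intensity gradient, as in radiographic crops
    img += 0.05 * (np.mgrid[0:side, 0:side][0] / side - 0.5) * (mask > 0)
    img = gaussian_filter(img, cfg.blur_sigma * side / 64.0)
    img += cfg.noise_sd * rng.standard_normal((side, side))
    img = np.clip(img, 0.0, 1.0)
    return RoiSample(
        image=img,
        mask=mask,
        grade_index=params.stage,
        bone=cfg.bone,
        sample_id=sample_id,
    )


def _make_set(cfg: SyntheticConfig, prefix: str, n_per_stage: int, seed: int) -> list[RoiSample]:
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * N_STAGES * n_per_stage) % 2**31
    samples: list[RoiSample] = []
    k = 0
    for stage in range(N_STAGES):
        for i in range(n_per_stage):
            params = stage_morphology(stage, jitter_seed=int(seeds[k]))
            sid = f"{prefix}_s{stage}_{i:04d}"
            samples.append(
                render_sample(params, cfg, noise_seed=int(seeds[k + 1]), sample_id=sid)
            )
            k += 2
    return samples


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[list[RoiSample], list[RoiSample], list[RoiSample]]:
    """Generate (pretrain, multi-task, independent test) sets.

    The three sets are disjoint by sample id, class-balanced, and
    bit-reproducible under ``cfg.seed``.  The pretrain set plays the role
    of the segmentation-only pool; the multi-task set carries masks and
    grades; the test set is never used for training.
    """
    root = np.random.SeedSequence(cfg.seed)
    s_pre, s_mt, s_test = (int(s % 2**31) for s in root.generate_state(3))
    pretrain = _make_set(cfg, "pre", cfg.n_per_stage_pretrain, s_pre)
    multitask = _make_set(cfg, "mt", cfg.n_per_stage, s_mt)
    test = _make_set(cfg, "test", cfg.n_per_stage_test, s_test)
    return pretrain, multitask, test


def write_dataset(out_dir: str | Path, samples: list[RoiSample]) -> None:
    """Write a sample list in the on-disk layout the training CLI consumes:
    images/<id>.png, masks/<id>.png, labels.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    codec = GradeCodec.for_bone(samples[0].bone) if samples else None
    rows = ["sample_id,bone,grade"]
    for s in samples:
        write_image(out / "images" / f"{s.sample_id}.png", s.image)
        if s.mask is not None:
            write_mask(out / "masks" / f"{s.sample_id}.png", s.mask)
        if s.grade_index is not None:
            rows.append(f"{s.sample_id},{s.bone},{codec.decode(s.grade_index)}")
    (out / "labels.csv").write_text("\n".join(rows) + "\n")
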