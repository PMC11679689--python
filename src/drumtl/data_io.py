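"""Reading, writing and preprocessing of ROI crops, masks and grade labels.

The unit of every pipeline is a :class:`RoiSample`: a single-channel
grayscale crop of the distal radius or ulna region, optionally paired with
a binary segmentation mask and a skeletal-maturity grade.  Grades follow
the distal radius and ulna (DRU) scheme restricted to the seven stages
spanning the pubertal growth period: R5..R11 for the radius and U3..U9 for
the ulna.  Grades below R5/U3 are rejected at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "RADIUS_GRADES",
    "ULNA_GRADES",
    "RoiSample",
    "GradeCodec",
    "SplitSpec",
    "pad_resize_to_square",
    "encode_grade",
    "decode_grade",
    "flip_horizontal_pair",
    "load_label_table",
    "make_splits",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "save_splits",
    "load_splits",
]

RADIUS_GRADES = tuple(f"R{i}" for i in range(5, 12))
ULNA_GRADES = tuple(f"U{i}" for i in range(3, 10))

N_STAGES = 7


@dataclass(frozen=True)
class GradeCodec:
    """Bijective mapping between the 7 ordinal grade names of one bone and
    the integer stage indices 0..6."""

    bone: str
    labels: tuple[str, ...]

    @classmethod
    def for_bone(cls, bone: str) -> "GradeCodec":
        if bone == "radius":
            return cls("radius", RADIUS_GRADES)
        if bone == "ulna":
            return cls("ulna", ULNA_GRADES)
        raise ValueError(f"unknown bone {bone!r}; expected 'radius' or 'ulna'")

    def encode(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"grade {label!r} is outside the supported {self.bone} range "
                f"{self.labels[0]}..{self.labels[-1]}"
            ) from None

    def decode(self, index: int) -> str:
        if not 0 <= index < len(self.labels):
            raise KeyError(f"stage index {index} outside [0, {len(self.labels) - 1}]")
        return self.labels[index]


def encode_grade(label: str, codec: GradeCodec) -> int:
    return codec.encode(label)


def decode_grade(index: int, codec: GradeCodec) -> str:
    return codec.decode(index)


@dataclass
class RoiSample:
    """One grayscale ROI crop with optional mask and grade label."""

    image: np.ndarray
    mask: np.ndarray | None = None
    grade_index: int | None = None
    bone: str = "radius"
    sample_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValueError("image must be a 2-D grayscale array")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape:
                raise ValueError("mask shape must match image shape")
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask must be binary")
            self.mask = self.mask.astype(np.uint8)
        if self.grade_index is not None and not 0 <= self.grade_index < N_STAGES:
            raise ValueError(f"grade_index must be in [0, {N_STAGES - 1}]")


def _scaled_shape(h: int, w: int, side: int) -> tuple[int, int]:
    if h >= w:
        return side, int(round(w * side / h))
    return int(round(h * side / w)), side


def pad_resize_to_square(
    image: np.ndarray, side: int, *, is_mask: bool = False
) -> np.ndarray:
    """Scale the longest dimension to ``side`` and zero-pad to a square.

    Aspect ratio is preserved; content is centred, with an odd padding
    remainder going to the right/bottom.  Images are interpolated
    bilinearly, masks with nearest-neighbour so they stay binary.
    """
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 1:
        raise ValueError("input must be a non-empty 2-D array")
    if side < 1:
        raise ValueError("side must be >= 1")
    h, w = image.shape
    nh, nw = _scaled_shape(h, w, side)
    if (nh, nw) != (h, w):
        order = 0 if is_mask else 1
        content = _sk_resize(
            image.astype(np.float64),
            (nh, nw),
            order=order,
            anti_aliasing=False,
            preserve_range=True,
        )
        if is_mask:
            content = (content > 0.5).astype(image.dtype)
    else:
        content = image
    out = np.zeros((side, side), dtype=content.dtype)
    top = (side - nh) // 2
    left = (side - nw) // 2
    out[top : top + nh, left : left + nw] = content
    return out


def flip_horizontal_pair(sample: RoiSample) -> RoiSample:
    """Mirror image and mask together about the vertical axis."""
    return replace(
        sample,
        image=sample.image[:, ::-1].copy(),
        mask=None if sample.mask is None else sample.mask[:, ::-1].copy(),
    )


def load_label_table(path: str | Path) -> list[tuple[str, str, int]]:
    """Parse a ``sample_id,bone,grade`` CSV into (id, bone, stage index) rows."""
    df = pd.read_csv(path, dtype=str)
    expected = ["sample_id", "bone", "grade"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)}")
    rows: list[tuple[str, str, int]] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        sid, bone, grade = rec.sample_id, rec.bone, rec.grade
        if pd.isna(sid) or pd.isna(bone) or pd.isna(grade):
            raise ValueError(f"{path}: malformed row {i}: {rec}")
        if sid in seen:
            raise ValueError(
                f"{path}: duplicate sample_id {sid!r} at row {i} (first at row {seen[sid]})"
            )
        seen[sid] = i
        try:
            codec = GradeCodec.for_bone(bone)
            idx = codec.encode(grade)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from None
        rows.append((sid, bone, idx))
    return rows


@dataclass(frozen=True)
class SplitSpec:
    role: str
    ids: tuple[str, ...]
    seed: int = 0


def make_splits(
    ids: Sequence[str],
    ratios: tuple[int, int, int] = (7, 1, 2),
    seed: int = 0,
    roles: tuple[str, str, str] = ("pretrain_train", "pretrain_val", "pretrain_test"),
) -> dict[str, SplitSpec]:
    """Seeded 7:1:2 partition; floor allocation with the remainder to train."""
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError(f"need at least 10 ids to split, got {len(ids)}")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    sizes = [len(ids) * r // total for r in ratios]
    sizes[0] += len(ids) - sum(sizes)
    out: dict[str, SplitSpec] = {}
    start = 0
    for role, size in zip(roles, sizes):
        out[role] = SplitSpec(role, tuple(order[start : start + size]), seed)
        start += size
    return out


# -- on-disk formats ----------------------------------------------------


def read_image(path: str | Path) -> np.ndarray:
    """Load a JPG/PNG crop as grayscale intensities in [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.float64)
    return arr / 255.0


def write_image(path: str | Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a PNG mask (foreground 255) as a binary uint8 array."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def save_splits(path: str | Path, splits: dict[str, SplitSpec]) -> None:
    payload = {role: list(spec.ids) for role, spec in splits.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_splits(path: str | Path) -> dict[str, SplitSpec]:
    payload = json.loads(Path(path).read_text())
    return {role: SplitSpec(role, tuple(ids)) for role, ids in payload.items()}
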