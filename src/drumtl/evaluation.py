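"""Evaluation: overlap metrics, stage-classification metrics, bootstrap CIs.

Segmentation is scored with IoU = |X ∩ Y| / |X ∪ Y| and the Dice
similarity coefficient DSC = 2|X ∩ Y| / (|X| + |Y|) on hard masks
(probabilities thresholded at 0.5).  Classification is scored with
accuracy and macro-averaged precision/recall/F1 over the 7 maturity
stages, plus a 7x7 confusion matrix (true rows x predicted columns).
Confidence intervals are percentile bootstrap (default 5000 resamples)
over test samples; when several repeated trainings are evaluated, the
point estimate is the mean over repeats and the bootstrap pools the
repeats' prediction sets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .data_io import GradeCodec, RoiSample
from .multitask import MultiTaskModel, predict_grade

__all__ = [
    "iou",
    "dsc",
    "ClassificationMetrics",
    "classification_metrics",
    "bootstrap_ci",
    "bootstrap_ci_values",
    "EvalReport",
    "evaluate_model",
    "predict_dataset",
]

SEG_THRESHOLD = 0.5


def _check_masks(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def iou(pred_mask, truth_mask) -> float:
    """Intersection over union of two binary masks; 1.0 when both empty."""
    p, t = _check_masks(pred_mask, truth_mask)
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def dsc(pred_mask, truth_mask) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    p, t = _check_masks(pred_mask, truth_mask)
    total = p.sum() + t.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / total)


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray  # true rows x predicted columns


def classification_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], k: int = 7
) -> ClassificationMetrics:
    """Accuracy, per-class and macro precision/recall/F1, confusion matrix.

    Macro averages are unweighted means over the classes present in
    ``y_true``; per-class ratios that are undefined (a class never
    predicted, or absent from the truth) are set to 0 with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label arrays")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.arange(k)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    present = np.isin(labels, y_true)
    predicted = np.isin(labels, y_pred)
    if np.any(present & ~predicted):
        warnings.warn(
            "precision undefined (class never predicted); reported as 0",
            RuntimeWarning,
        )
    acc = float((y_true == y_pred).mean())
    return ClassificationMetrics(
        accuracy=acc,
        precision=prec,
        recall=rec,
        f1=f1,
        macro_precision=float(prec[present].mean()),
        macro_recall=float(rec[present].mean()),
        macro_f1=float(f1[present].mean()),
        confusion=conf,
    )


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    y_true,
    y_pred,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap over (true, pred) pairs.

    Returns (point estimate, lower, upper).  Resamples on which the metric
    is undefined (NaN) are redrawn; the redraw count is reported in a
    warning.  Deterministic under ``seed``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = y_true.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs at least 2 samples")
    rng = np.random.default_rng(seed)
    point = float(metric_fn(y_true, y_pred))
    vals = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            v = float(metric_fn(y_true[idx], y_pred[idx]))
            if np.isfinite(v):
                break
            redraws += 1
        vals[b] = v
    if redraws:
        warnings.warn(f"{redraws} bootstrap resamples redrawn", RuntimeWarning)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return point, float(lo), float(hi)


def bootstrap_ci_values(
    values, n_boot: int = 5000, level: float = 0.95, seed: int = 0
) -> tuple[float, float, float]:
    """Bootstrap CI of the mean of per-sample scores."""
    values = np.asarray(values, dtype=float)
    return bootstrap_ci(
        lambda t, _p: t.mean(), values, values, n_boot=n_boot, level=level, seed=seed
    )


def _macro_prf(y_true: np.ndarray, y_pred: np.ndarray, k: int = 7) -> tuple[float, float, float]:
    """Vectorised macro precision/recall/F1 over classes present in y_true
    (undefined ratios contribute 0), for use inside the bootstrap loop."""
    conf = np.bincount(y_true * k + y_pred, minlength=k * k).reshape(k, k)
    tp = np.diag(conf).astype(float)
    pred_tot = conf.sum(axis=0).astype(float)
    true_tot = conf.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    present = true_tot > 0
    return float(prec[present].mean()), float(rec[present].mean()), float(f1[present].mean())


_FAST_METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "accuracy": lambda t, p: float((t == p).mean()),
    "macro_precision": lambda t, p: _macro_prf(t, p)[0],
    "macro_recall": lambda t, p: _macro_prf(t, p)[1],
    "macro_f1": lambda t, p: _macro_prf(t, p)[2],
}


@dataclass
class EvalReport:
    """Per-bone segmentation and classification report with 95% CIs.

    Every metric entry is (point, ci_lower, ci_upper).  With several
    repeated trainings the point estimate is the mean over repeats and the
    confusion matrix counts the pooled predictions (row sums are then
    ``repeats x`` the per-class test counts).
    """

    bone: str
    seg: dict[str, tuple[float, float, float]]
    cls: dict[str, tuple[float, float, float]]
    confusion: np.ndarray
    n_test: int
    n_boot: int
    repeats: int
    per_class: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bone": self.bone,
            "seg": {k: list(v) for k, v in self.seg.items()},
            "cls": {k: list(v) for k, v in self.cls.items()},
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "n_test": self.n_test,
            "n_boot": self.n_boot,
            "repeats": self.repeats,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def save_confusion_csv(self, path: str | Path, codec: GradeCodec) -> None:
        df = pd.DataFrame(self.confusion, index=codec.labels, columns=codec.labels)
        df.to_csv(path, index_label="true\\pred")


def _batches(n: int, size: int):
    for start in range(0, n, size):
        yield slice(start, min(start + size, n))


def predict_dataset(
    model: MultiTaskModel,
    samples: Sequence[RoiSample],
    codec: GradeCodec,
    batch_size: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the model over a dataset; returns (predicted stage indices,
    predicted hard masks (N, H, W)), ordered as ``samples``."""
    was_training = model.training
    model.eval()
    dt = model.backbone_config.np_dtype
    preds: list[int] = []
    masks: list[np.ndarray] = []
    try:
        for sl in _batches(len(samples), batch_size):
            batch = samples[sl]
            x = np.stack([s.image for s in batch])[:, None].astype(dt)
            out = model(x)
            labels = predict_grade(out, codec)
            preds.extend(codec.encode(g) for g in labels)
            masks.append((out.seg_prob.data[:, 0] > SEG_THRESHOLD).astype(np.uint8))
    finally:
        model.train(was_training)
    return np.asarray(preds), np.concatenate(masks)


def evaluate_model(
    models: MultiTaskModel | Sequence[MultiTaskModel],
    test_set: Sequence[RoiSample],
    codec: GradeCodec,
    n_boot: int = 5000,
    seed: int = 0,
    train_ids: set[str] | None = None,
    batch_size: int = 16,
) -> EvalReport:
    """Full test-set evaluation of one model or several repeated trainings.

    ``train_ids`` enables the leakage guard: any overlap between training
    and test sample ids is a hard error.
    """
    if isinstance(models, MultiTaskModel):
        models = [models]
    if not test_set:
        raise ValueError("empty test set")
    if train_ids is not None:
        overlap = train_ids & {s.sample_id for s in test_set}
        if overlap:
            raise ValueError(f"test samples seen in training: {sorted(overlap)[:5]}")
    y_true = np.asarray([s.grade_index for s in test_set], dtype=int)

    pooled_pred: list[np.ndarray] = []
    pooled_iou: list[float] = []
    pooled_dsc: list[float] = []
    per_repeat: list[ClassificationMetrics] = []
    per_repeat_seg: list[tuple[float, float]] = []
    for model in models:
        pred_idx, pred_masks = predict_dataset(model, test_set, codec, batch_size)
        pooled_pred.append(pred_idx)
        per_repeat.append(classification_metrics(y_true, pred_idx))
        ious = [iou(pm, s.mask) for pm, s in zip(pred_masks, test_set) if s.mask is not None]
        dscs = [dsc(pm, s.mask) for pm, s in zip(pred_masks, test_set) if s.mask is not None]
        pooled_iou.extend(ious)
        pooled_dsc.extend(dscs)
        per_repeat_seg.append((float(np.mean(ious)), float(np.mean(dscs))))

    repeats = len(models)
    # point estimates: mean over repeats; CIs: bootstrap over pooled samples
    seed_seq = np.random.SeedSequence(seed).generate_state(6)
    pooled_true = np.tile(y_true, repeats)
    pooled = np.concatenate(pooled_pred)

    def _cls_ci(attr: str, s: int) -> tuple[float, float, float]:
        point = float(np.mean([getattr(m, attr) for m in per_repeat]))
        _, lo, hi = bootstrap_ci(
            _FAST_METRICS[attr],
            pooled_true,
            pooled,
            n_boot=n_boot,
            seed=int(seed_seq[s] % 2**31),
        )
        return point, lo, hi

    cls = {
        "accuracy": _cls_ci("accuracy", 0),
        "macro_precision": _cls_ci("macro_precision", 1),
        "macro_recall": _cls_ci("macro_recall", 2),
        "macro_f1": _cls_ci("macro_f1", 3),
    }
    seg = {}
    if pooled_iou:
        iou_point = float(np.mean([s[0] for s in per_repeat_seg]))
        dsc_point = float(np.mean([s[1] for s in per_repeat_seg]))
        _, lo, hi = bootstrap_ci_values(pooled_iou, n_boot, seed=int(seed_seq[4] % 2**31))
        seg["iou"] = (iou_point, lo, hi)
        _, lo, hi = bootstrap_ci_values(pooled_dsc, n_boot, seed=int(seed_seq[5] % 2**31))
        seg["dsc"] = (dsc_point, lo, hi)

    confusion = sum(m.confusion for m in per_repeat)
    per_class = {
        "precision": np.mean([m.precision for m in per_repeat], axis=0).tolist(),
        "recall": np.mean([m.recall for m in per_repeat], axis=0).tolist(),
        "f1": np.mean([m.f1 for m in per_repeat], axis=0).tolist(),
    }
    return EvalReport(
        bone=codec.bone,
        seg=seg,
        cls=cls,
        confusion=confusion,
        n_test=len(test_set),
        n_boot=n_boot,
        repeats=repeats,
        per_class=per_class,
    )
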