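"""Two-phase transfer-learning protocol and ablation variants.

Phase 1 pretrains the attention U-Net backbone on a segmentation-only pool
split 7:1:2 into train/validation/test, selecting on validation Dice.
Phase 2 builds the multi-task model, initialises its shared encoder (and
bridge) from the pretrained backbone, and trains under the combined loss
L_m = lambda * L_seg + (1 - lambda) * L_cla with five-fold stratified
cross-validation, horizontal-flip augmentation of the training folds, and
Adam (batch 16, learning rate 0.005 with step decay).

Variants mirror the ablation settings: ``unet_backbone`` removes the
attention gates, ``no_pretrain`` skips encoder transfer, ``regression_head``
replaces the softmax with a single ReLU unit trained on squared error of
the stage index, and ``two_stage`` segments first with the pretrained
backbone and classifies the hard-masked image with a separately trained
classifier on the same architecture.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data_io import GradeCodec, RoiSample, flip_horizontal_pair, make_splits
from .evaluation import (
    EvalReport,
    bootstrap_ci_values,
    dsc,
    evaluate_model,
    iou,
    predict_dataset,
)
from .losses import (
    combined_loss,
    cross_entropy_from_logits,
    dice_loss,
    mse_stage_loss,
)
from .multitask import (
    REGRESSOR,
    SOFTMAX,
    ClassHeadConfig,
    MultiTaskModel,
    transfer_encoder_parameters,
)
from .networks import AttentionUNet, BackboneConfig
from .nn import Adam, StepDecay

__all__ = [
    "TrainConfig",
    "VARIANTS",
    "PretrainResult",
    "MultiTaskResult",
    "pretrain_backbone",
    "train_multitask",
    "sweep_lambda",
    "run_variant",
    "encoder_hash",
]

log = logging.getLogger(__name__)

VARIANTS = ("proposed", "unet_backbone", "no_pretrain", "regression_head", "two_stage")


@dataclass(frozen=True)
class TrainConfig:
    """Every fixed hyperparameter of the training protocol."""

    batch_size: int = 16
    initial_lr: float = 0.005
    lr_decay_every: int = 10
    lr_decay_factor: float = 0.5
    epochs: int = 50
    pretrain_epochs: int = 50
    folds: int = 5
    lambda_weight: float = 0.4
    smooth_theta: float = 1.0
    augmentation: bool = True
    patience: int = 10
    seed: int = 0
    variant: str = "proposed"
    # architecture
    levels: int = 5
    base_channels: int = 32
    use_batchnorm: bool = True
    side: int = 256
    dropout_rate: float = 0.3
    # protocol switches
    run_cv: bool = True
    final_model: str = "refit"  # or "ensemble"
    transfer_include_bridge: bool = True
    eval_n_boot: int = 5000

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected {VARIANTS}")
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must be in [0, 1]")
        if self.final_model not in ("refit", "ensemble"):
            raise ValueError("final_model must be 'refit' or 'ensemble'")

    def backbone_config(self) -> BackboneConfig:
        return BackboneConfig(
            levels=self.levels,
            base_channels=self.base_channels,
            use_attention=self.variant != "unet_backbone",
            use_batchnorm=self.use_batchnorm,
            side=self.side,
        )

    def head_config(self) -> ClassHeadConfig:
        kind = REGRESSOR if self.variant == "regression_head" else SOFTMAX
        return ClassHeadConfig(dropout_rate=self.dropout_rate, head_kind=kind)


def _derive_seeds(master: int, n: int, tag: int) -> list[int]:
    """Fan a master seed out into independent sub-streams (< 2**31)."""
    return [int(s % 2**31) for s in np.random.SeedSequence([master, tag]).generate_state(n)]


def encoder_hash(module, include_bridge: bool = True) -> str:
    """SHA-256 over the shared-trunk parameter tensors, for transfer audits."""
    prefixes = ("encoder_blocks.", "bridge.") if include_bridge else ("encoder_blocks.",)
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        if name.startswith(prefixes):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data, dtype=np.float64).tobytes())
    return h.hexdigest()


# ----------------------------------------------------------------------
# generic mini-batch loop


def _stack_batch(samples: Sequence[RoiSample], dtype):
    x = np.stack([s.image for s in samples])[:, None].astype(dtype)
    masks = (
        np.stack([s.mask for s in samples])[:, None].astype(dtype)
        if samples[0].mask is not None
        else None
    )
    labels = (
        np.asarray([s.grade_index for s in samples], dtype=int)
        if samples[0].grade_index is not None
        else None
    )
    return x, masks, labels


def _loss_terms(model_out, masks, labels, config: TrainConfig):
    l_seg = dice_loss(model_out.seg_prob, masks, config.smooth_theta)
    if model_out.class_prob is not None:
        # log-softmax path: same value as CE on the softmax probabilities,
        # but stable when a true-class probability underflows float32
        l_cla = cross_entropy_from_logits(model_out.class_logits, labels)
    else:
        l_cla = mse_stage_loss(model_out.stage_value, labels)
    return l_seg, l_cla, combined_loss(l_seg, l_cla, config.lambda_weight)


def _eval_multitask_loss(model: MultiTaskModel, samples, config: TrainConfig) -> float:
    model.eval()
    dt = model.backbone_config.np_dtype
    total, n = 0.0, 0
    for sl in _slices(len(samples), config.batch_size):
        batch = samples[sl]
        x, masks, labels = _stack_batch(batch, dt)
        _, _, l_m = _loss_terms(model(x), masks, labels, config)
        total += float(l_m) * len(batch)
        n += len(batch)
    model.train()
    return total / n


def _slices(n: int, size: int):
    return [slice(i, min(i + size, n)) for i in range(0, n, size)]


def _augment(samples: list[RoiSample]) -> list[RoiSample]:
    """Deterministic doubling: originals followed by their mirror images."""
    return list(samples) + [flip_horizontal_pair(s) for s in samples]


# ----------------------------------------------------------------------
# phase 1: backbone pretraining


@dataclass
class PretrainResult:
    backbone: AttentionUNet
    test_iou: float
    test_dsc: float
    split_sizes: tuple[int, int, int]
    history: list[dict]


def pretrain_backbone(
    seg_dataset: Sequence[RoiSample], config: TrainConfig
) -> PretrainResult:
    """Pretrain the segmentation backbone on a mask-only pool (7:1:2 split).

    The model with the best validation Dice loss is kept; IoU/DSC are
    reported on the held-out test share.
    """
    if not seg_dataset or seg_dataset[0].mask is None:
        raise ValueError("pretraining requires samples with masks")
    split_seed, init_seed, shuffle_seed = _derive_seeds(config.seed, 3, tag=10)
    by_id = {s.sample_id: s for s in seg_dataset}
    splits = make_splits(list(by_id), seed=split_seed)
    train = [by_id[i] for i in splits["pretrain_train"].ids]
    val = [by_id[i] for i in splits["pretrain_val"].ids]
    test = [by_id[i] for i in splits["pretrain_test"].ids]
    if not train or not val or not test:
        raise ValueError("a pretraining split is empty")

    cfg = config.backbone_config()
    log.info("pretraining backbone: %s", cfg)
    model = AttentionUNet(cfg, seed=init_seed)
    opt = Adam(model.parameters(), lr=config.initial_lr)
    sched = StepDecay(opt, config.lr_decay_every, config.lr_decay_factor)
    rng = np.random.default_rng(shuffle_seed)
    dt = cfg.np_dtype

    def val_loss() -> float:
        model.eval()
        tot = 0.0
        for sl in _slices(len(val), config.batch_size):
            batch = val[sl]
            x, masks, _ = _stack_batch(batch, dt)
            tot += float(dice_loss(model(x).seg_prob, masks, config.smooth_theta)) * len(batch)
        model.train()
        return tot / len(val)

    best = (np.inf, model.state_dict())
    history: list[dict] = []
    bad_epochs = 0
    model.train()
    for epoch in range(config.pretrain_epochs):
        sched.at_epoch(epoch)
        order = rng.permutation(len(train))
        ep_loss = 0.0
        for sl in _slices(len(train), config.batch_size):
            batch = [train[i] for i in order[sl]]
            x, masks, _ = _stack_batch(batch, dt)
            loss = dice_loss(model(x).seg_prob, masks, config.smooth_theta)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss) * len(batch)
        vl = val_loss()
        history.append({"epoch": epoch, "l_seg": ep_loss / len(train), "val_l_seg": vl})
        if vl < best[0] - 1e-6:
            best = (vl, model.state_dict())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                log.info("pretraining early stop at epoch %d", epoch)
                break
    model.load_state_dict(best[1])
    model.eval()

    pred = np.concatenate(
        [model.predict_mask(_stack_batch(test[sl], dt)[0]) for sl in _slices(len(test), config.batch_size)]
    )
    ious = [iou(p, s.mask) for p, s in zip(pred, test)]
    dscs = [dsc(p, s.mask) for p, s in zip(pred, test)]
    return PretrainResult(
        backbone=model,
        test_iou=float(np.mean(ious)),
        test_dsc=float(np.mean(dscs)),
        split_sizes=(len(train), len(val), len(test)),
        history=history,
    )


# ----------------------------------------------------------------------
# phase 2: multi-task training


@dataclass
class MultiTaskResult:
    final_model: MultiTaskModel
    fold_models: list[MultiTaskModel]
    fold_metrics: list[dict]
    history: list[dict]
    step0_encoder_hash: str
    transferred: list[str]
    init_state: dict = field(default_factory=dict)  # fold-0 weights at step 0


def _train_one(
    model: MultiTaskModel,
    train: list[RoiSample],
    val: list[RoiSample] | None,
    config: TrainConfig,
    shuffle_seed: int,
    fold: int,
    history: list[dict],
) -> None:
    opt = Adam(model.parameters(), lr=config.initial_lr)
    sched = StepDecay(opt, config.lr_decay_every, config.lr_decay_factor)
    rng = np.random.default_rng(shuffle_seed)
    dt = model.backbone_config.np_dtype
    best = (np.inf, None)
    bad = 0
    model.train()
    for epoch in range(config.epochs):
        sched.at_epoch(epoch)
        order = rng.permutation(len(train))
        e_seg = e_cla = e_m = 0.0
        for sl in _slices(len(train), config.batch_size):
            batch = [train[i] for i in order[sl]]
            x, masks, labels = _stack_batch(batch, dt)
            l_seg, l_cla, l_m = _loss_terms(model(x), masks, labels, config)
            opt.zero_grad()
            l_m.backward()
            opt.step()
            e_seg += float(l_seg) * len(batch)
            e_cla += float(l_cla) * len(batch)
            e_m += float(l_m) * len(batch)
        rec = {
            "epoch": epoch,
            "fold": fold,
            "l_seg": e_seg / len(train),
            "l_cla": e_cla / len(train),
            "l_m": e_m / len(train),
        }
        if val:
            rec["val_l_m"] = _eval_multitask_loss(model, val, config)
            if rec["val_l_m"] < best[0] - 1e-6:
                best = (rec["val_l_m"], model.state_dict())
                bad = 0
            else:
                bad += 1
        history.append(rec)
        if val and bad >= config.patience:
            log.info("fold %d early stop at epoch %d", fold, epoch)
            break
    if val and best[1] is not None:
        model.load_state_dict(best[1])


def _fold_indices(labels: np.ndarray, config: TrainConfig, seed: int):
    counts = np.bincount(labels, minlength=7)
    min_count = counts[counts > 0].min()
    n_splits = int(config.folds)
    if min_count < n_splits:
        n_splits = max(2, int(min_count))
        log.warning(
            "some stages have fewer samples (%s) than folds=%d; "
            "reducing to %d stratified folds",
            counts.tolist(),
            config.folds,
            n_splits,
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % 2**31)
    return list(skf.split(np.zeros(len(labels)), labels))


def train_multitask(
    mt_dataset: Sequence[RoiSample],
    pretrained_backbone: AttentionUNet | None,
    config: TrainConfig,
) -> MultiTaskResult:
    """Cross-validated multi-task training with optional encoder transfer.

    With ``config.run_cv`` the dataset is split into ``folds`` stratified
    folds; each fold trains a fresh model (encoder transferred unless the
    variant is ``no_pretrain``), training folds are doubled by horizontal
    flip, and validation folds are never augmented.  The final model is a
    refit on all samples (default) or the fold ensemble.  Without
    ``run_cv`` a single stratified 90/10 split is used (fast path for
    scaled-down experiments); fold 0 then denotes that single split.
    """
    mt_dataset = list(mt_dataset)
    if not mt_dataset or mt_dataset[0].mask is None or mt_dataset[0].grade_index is None:
        raise ValueError("multi-task training requires masks and grade labels")
    if config.variant == "no_pretrain":
        pretrained_backbone = None
    elif config.variant != "two_stage" and pretrained_backbone is None and config.variant in ("proposed", "unet_backbone", "regression_head"):
        log.warning("no pretrained backbone supplied; proceeding with fresh init")

    labels = np.asarray([s.grade_index for s in mt_dataset])
    cv_seed, shuffle_seed0, init_seed0 = _derive_seeds(config.seed, 3, tag=20)
    history: list[dict] = []
    fold_models: list[MultiTaskModel] = []
    fold_metrics: list[dict] = []
    step0_hash = ""
    transferred: list[str] = []

    def build_model(seed: int) -> tuple[MultiTaskModel, list[str]]:
        model = MultiTaskModel(config.backbone_config(), config.head_config(), seed=seed)
        names: list[str] = []
        if pretrained_backbone is not None:
            _, names = transfer_encoder_parameters(
                pretrained_backbone, model, include_bridge=config.transfer_include_bridge
            )
        return model, names

    if config.run_cv:
        folds = _fold_indices(labels, config, cv_seed)
    else:
        # single stratified holdout: 10%, but at least one sample per class
        classes, counts = np.unique(labels, return_counts=True)
        n_val = max(int(np.ceil(0.1 * len(labels))), len(classes))
        stratify = labels if counts.min() >= 2 and n_val < len(labels) else None
        if stratify is None:
            log.warning("holdout cannot be stratified; falling back to random split")
        tr_idx, va_idx = train_test_split(
            np.arange(len(labels)),
            test_size=min(n_val, len(labels) - len(classes)),
            random_state=cv_seed % 2**31,
            stratify=stratify,
        )
        folds = [(tr_idx, va_idx)]

    init_state: dict = {}
    for k, (tr_idx, va_idx) in enumerate(folds):
        model, names = build_model(init_seed0 + k)
        if k == 0:
            # transfer must precede the first gradient step: audit hash now
            step0_hash = encoder_hash(model.backbone, config.transfer_include_bridge)
            transferred = names
            init_state = model.state_dict()
        train_fold = [mt_dataset[i] for i in tr_idx]
        if config.augmentation:
            train_fold = _augment(train_fold)
        val_fold = [mt_dataset[i] for i in va_idx]
        _train_one(model, train_fold, val_fold, config, shuffle_seed0 + k, k, history)
        codec = GradeCodec.for_bone(mt_dataset[0].bone)
        pred_idx, pred_masks = predict_dataset(model, val_fold, codec, config.batch_size)
        val_true = np.asarray([s.grade_index for s in val_fold])
        fold_metrics.append(
            {
                "fold": k,
                "val_accuracy": float((pred_idx == val_true).mean()),
                "val_dsc": float(
                    np.mean([dsc(p, s.mask) for p, s in zip(pred_masks, val_fold)])
                ),
                "n_train": len(train_fold),
                "n_val": len(val_fold),
            }
        )
        fold_models.append(model)

    if config.final_model == "ensemble" and config.run_cv:
        final = fold_models
        final_model = fold_models[0]
    else:
        final_model, names = build_model(init_seed0 + 1000)
        if not config.run_cv and fold_models:
            # fast path: the single trained split model is the final model
            final_model = fold_models[0]
        else:
            refit = _augment(mt_dataset) if config.augmentation else list(mt_dataset)
            _train_one(final_model, refit, None, config, shuffle_seed0 + 1000, -1, history)

    return MultiTaskResult(
        final_model=final_model,
        fold_models=fold_models,
        fold_metrics=fold_metrics,
        history=history,
        step0_encoder_hash=step0_hash,
        transferred=transferred,
        init_state=init_state,
    )


def sweep_lambda(
    mt_dataset: Sequence[RoiSample],
    grid: Sequence[float],
    config: TrainConfig,
    pretrained_backbone: AttentionUNet | None = None,
) -> list[dict]:
    """Cross-validated accuracy for each task weight in ``grid``.

    Returns one row per lambda with mean +/- sd of fold validation
    accuracy; the selection rule is argmax of the mean.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty lambda grid")
    rows: list[dict] = []
    for lam in grid:
        res = train_multitask(
            mt_dataset, pretrained_backbone, replace(config, lambda_weight=float(lam))
        )
        accs = [m["val_accuracy"] for m in res.fold_metrics]
        rows.append(
            {
                "lambda": float(lam),
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs)),
                "fold_accuracies": accs,
            }
        )
    best = max(rows, key=lambda r: r["mean_accuracy"])
    for r in rows:
        r["selected"] = r is best
    return rows


# ----------------------------------------------------------------------
# ablation variants


def _mask_images(model: AttentionUNet, samples: list[RoiSample], batch: int) -> list[RoiSample]:
    """image <- image * predicted mask (hard masking for the two-stage path)."""
    dt = model.config.np_dtype
    out: list[RoiSample] = []
    for sl in _slices(len(samples), batch):
        chunk = samples[sl]
        x = np.stack([s.image for s in chunk])[:, None].astype(dt)
        masks = model.predict_mask(x)
        for s, m in zip(chunk, masks):
            out.append(
                RoiSample(
                    image=s.image * m,
                    mask=s.mask,
                    grade_index=s.grade_index,
                    bone=s.bone,
                    sample_id=s.sample_id,
                )
            )
    return out


def run_variant(
    variant: str,
    datasets: tuple[Sequence[RoiSample], Sequence[RoiSample], Sequence[RoiSample]],
    config: TrainConfig,
) -> tuple[EvalReport, MultiTaskResult]:
    """Run one full pipeline variant and evaluate on the independent test set.

    ``datasets`` is (segmentation pretrain pool, multi-task set, test set).
    All variants produce an :class:`EvalReport` with identical schema.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    config = replace(config, variant=variant)
    pretrain_set, mt_set, test_set = (list(d) for d in datasets)
    codec = GradeCodec.for_bone(mt_set[0].bone)
    train_ids = {s.sample_id for s in pretrain_set} | {s.sample_id for s in mt_set}

    backbone = None
    if variant in ("proposed", "unet_backbone", "regression_head", "two_stage"):
        backbone = pretrain_backbone(pretrain_set, config).backbone

    if variant == "two_stage":
        mt_masked = _mask_images(backbone, mt_set, config.batch_size)
        test_masked = _mask_images(backbone, test_set, config.batch_size)
        cls_config = replace(config, lambda_weight=0.0)
        result = train_multitask(mt_masked, None, cls_config)
        report = evaluate_model(
            result.final_model,
            test_masked,
            codec,
            n_boot=config.eval_n_boot,
            seed=config.seed,
            train_ids=train_ids,
            batch_size=config.batch_size,
        )
        # segmentation credit belongs to the first-stage backbone
        dt = backbone.config.np_dtype
        pred = np.concatenate(
            [
                backbone.predict_mask(np.stack([s.image for s in test_set[sl]])[:, None].astype(dt))
                for sl in _slices(len(test_set), config.batch_size)
            ]
        )
        ious = [iou(p, s.mask) for p, s in zip(pred, test_set)]
        dscs = [dsc(p, s.mask) for p, s in zip(pred, test_set)]
        sd = np.random.SeedSequence([config.seed, 99]).generate_state(2)
        report.seg["iou"] = bootstrap_ci_values(ious, config.eval_n_boot, seed=int(sd[0] % 2**31))
        report.seg["dsc"] = bootstrap_ci_values(dscs, config.eval_n_boot, seed=int(sd[1] % 2**31))
        return report, result

    result = train_multitask(mt_set, backbone, config)
    models = result.fold_models if config.final_model == "ensemble" else result.final_model
    report = evaluate_model(
        models,
        test_set,
        codec,
        n_boot=config.eval_n_boot,
        seed=config.seed,
        train_ids=train_ids,
        batch_size=config.batch_size,
    )
    return report, result
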