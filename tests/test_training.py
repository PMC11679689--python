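"""Training-protocol contracts at miniature scale: splits, transfer timing,
augmentation bookkeeping, variant switches, determinism."""

import numpy as np
import pytest

from drumtl.networks import AttentionUNet
from drumtl.training import (
    TrainConfig,
    VARIANTS,
    encoder_hash,
    pretrain_backbone,
    run_variant,
    sweep_lambda,
    train_multitask,
)

TINY = dict(
    side=32,
    base_channels=4,
    pretrain_epochs=1,
    epochs=1,
    run_cv=False,
    eval_n_boot=50,
    seed=3,
)


@pytest.fixture(scope="module")
def tiny_pretrained(small_dataset):
    pre, _, _ = small_dataset
    return pretrain_backbone(pre, TrainConfig(**TINY))


class TestTrainConfig:
    def test_defaults_match_protocol(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 16
        assert cfg.initial_lr == 0.005
        assert cfg.folds == 5
        assert cfg.lambda_weight == 0.4

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(variant="bogus")
        with pytest.raises(ValueError):
            TrainConfig(lambda_weight=1.5)


class TestPretrain:
    def test_split_ratio_7_1_2(self, small_dataset):
        pre, _, _ = small_dataset
        result = pretrain_backbone(pre, TrainConfig(**TINY))
        n = len(pre)
        tr, va, te = result.split_sizes
        assert tr + va + te == n
        assert tr == n - n * 1 // 10 - n * 2 // 10  # floors, remainder to train

    def test_rerun_same_seed_identical(self, small_dataset):
        pre, _, _ = small_dataset
        a = pretrain_backbone(pre, TrainConfig(**TINY))
        b = pretrain_backbone(pre, TrainConfig(**TINY))
        assert a.history == b.history
        assert encoder_hash(a.backbone) == encoder_hash(b.backbone)

    def test_requires_masks(self, small_dataset):
        _, mt, _ = small_dataset
        stripped = [type(s)(image=s.image, sample_id=s.sample_id) for s in mt[:12]]
        with pytest.raises(ValueError):
            pretrain_backbone(stripped, TrainConfig(**TINY))


class TestMultiTaskProtocol:
    def test_cv_folds_partition_and_stratify(self, small_dataset):
        _, mt, _ = small_dataset  # 3 per stage
        cfg = TrainConfig(**{**TINY, "run_cv": True, "folds": 3})
        result = train_multitask(mt, None, cfg)
        assert len(result.fold_metrics) == 3
        val_sizes = [m["n_val"] for m in result.fold_metrics]
        assert sum(val_sizes) == len(mt)  # validation folds partition the set
        assert all(v == 7 for v in val_sizes)  # one sample per stage per fold

    def test_augmentation_doubles_train_not_val(self, small_dataset):
        _, mt, _ = small_dataset
        cfg = TrainConfig(**{**TINY, "run_cv": True, "folds": 3})
        result = train_multitask(mt, None, cfg)
        for m in result.fold_metrics:
            assert m["n_train"] == 2 * (len(mt) - m["n_val"])
            assert m["n_val"] == len(mt) // 3

    def test_augmentation_off(self, small_dataset):
        _, mt, _ = small_dataset
        cfg = TrainConfig(**{**TINY, "run_cv": True, "folds": 3, "augmentation": False})
        result = train_multitask(mt, None, cfg)
        for m in result.fold_metrics:
            assert m["n_train"] == len(mt) - m["n_val"]

    def test_transfer_precedes_first_step(self, small_dataset, tiny_pretrained):
        _, mt, _ = small_dataset
        result = train_multitask(mt, tiny_pretrained.backbone, TrainConfig(**TINY))
        assert result.step0_encoder_hash == encoder_hash(tiny_pretrained.backbone)
        assert result.transferred  # parameter-by-parameter audit trail

    def test_no_pretrain_skips_transfer(self, small_dataset, tiny_pretrained):
        _, mt, _ = small_dataset
        cfg = TrainConfig(**{**TINY, "variant": "no_pretrain"})
        result = train_multitask(mt, tiny_pretrained.backbone, cfg)
        assert result.transferred == []
        assert result.step0_encoder_hash != encoder_hash(tiny_pretrained.backbone)

    def test_determinism_same_seed(self, small_dataset):
        _, mt, _ = small_dataset
        a = train_multitask(mt, None, TrainConfig(**TINY))
        b = train_multitask(mt, None, TrainConfig(**TINY))
        assert a.history == b.history

    def test_loss_logged_per_epoch(self, small_dataset):
        _, mt, _ = small_dataset
        cfg = TrainConfig(**{**TINY, "epochs": 2})
        result = train_multitask(mt, None, cfg)
        recs = [r for r in result.history if r["fold"] == 0]
        assert len(recs) == 2
        assert {"l_seg", "l_cla", "l_m"} <= set(recs[0])

    def test_requires_labels_and_masks(self, small_dataset):
        _, mt, _ = small_dataset
        unlabelled = [
            type(s)(image=s.image, mask=s.mask, sample_id=s.sample_id) for s in mt
        ]
        with pytest.raises(ValueError):
            train_multitask(unlabelled, None, TrainConfig(**TINY))


class TestLossTrend:
    def test_training_loss_decreases_on_small_synthetic_set(self):
        """Combined loss trends downward over epochs on a ~50-sample set
        for the large majority of seeds (smoke property)."""
        from drumtl.synthetic import SyntheticConfig, generate_dataset

        improved = 0
        for seed in (0, 1, 2):
            _, mt, _ = generate_dataset(
                SyntheticConfig(
                    side=32, n_per_stage=7, n_per_stage_pretrain=2,
                    n_per_stage_test=2, seed=300 + seed,
                )
            )
            cfg = TrainConfig(
                side=32, base_channels=4, epochs=3, run_cv=False,
                augmentation=False, seed=seed, eval_n_boot=50,
            )
            result = train_multitask(mt, None, cfg)
            losses = [r["l_m"] for r in result.history if r["fold"] == 0]
            improved += losses[-1] < losses[0]
        assert improved >= 2


class TestSweepLambda:
    def test_table_contract(self, small_dataset):
        _, mt, _ = small_dataset
        rows = sweep_lambda(mt, [0.0, 0.4], TrainConfig(**TINY))
        assert [r["lambda"] for r in rows] == [0.0, 0.4]
        assert all({"mean_accuracy", "sd_accuracy", "selected"} <= set(r) for r in rows)
        assert sum(r["selected"] for r in rows) == 1

    def test_empty_grid_rejected(self, small_dataset):
        _, mt, _ = small_dataset
        with pytest.raises(ValueError):
            sweep_lambda(mt, [], TrainConfig(**TINY))


class TestVariants:
    def test_unknown_variant_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            run_variant("efficientnet", small_dataset, TrainConfig(**TINY))

    def test_unet_backbone_has_no_gates(self):
        cfg = TrainConfig(**{**TINY, "variant": "unet_backbone"})
        model = AttentionUNet(cfg.backbone_config(), seed=0)
        assert not any(n.startswith("gates.") for n, _ in model.named_parameters())

    def test_regression_variant_head(self):
        cfg = TrainConfig(**{**TINY, "variant": "regression_head"})
        assert cfg.head_config().head_kind == "relu_regressor"

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_variants_share_report_schema(self, variant, small_dataset):
        report, _ = run_variant(variant, small_dataset, TrainConfig(**TINY))
        assert set(report.cls) == {"accuracy", "macro_precision", "macro_recall", "macro_f1"}
        assert set(report.seg) == {"iou", "dsc"}
        assert report.confusion.shape == (7, 7)
        assert report.confusion.sum() == report.n_test
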