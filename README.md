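# drumtl — attention multi-task learning for distal radius/ulna maturity grading

Skeletal maturity in children and adolescents is commonly read from
hand–wrist radiographs. The distal radius and ulna (DRU) scheme grades the
two bones on ordinal stages — the growth-plate gap narrows, the epiphysis
caps the metaphysis around the pubertal growth peak, and the plate fuses at
maturity — and is practical enough for routine scoliosis management, but
manual grading is slow and subjective. `drumtl` implements an automated
grader for single-bone ROI crops: a multi-task network that **jointly
segments the bone and classifies its maturity stage** (7 stages per bone:
radius R5–R11, ulna U3–U9), built for researchers who want to study the
interplay of boundary segmentation and ordinal stage classification.

The core model is an attention-gated U-Net backbone with a hard-shared
encoder feeding two branches:

* segmentation: the gated U-Net decoder, trained with smoothed Dice loss
  `L_seg = 1 − (2|X∩Y| + θ)/(|X|+|Y|+θ)`;
* grading: global-average-pooled features from the last encoder block, the
  bridge and the first decoder block, concatenated into a dense
  256 → 128 → 7 softmax head, trained with cross-entropy `L_cla`;

optimised jointly as `L_m = λ·L_seg + (1−λ)·L_cla` with λ = 0.4. Skip
connections pass through additive attention gates
`α = σ₂(ψ(σ₁(W_x·x + W_g·g + b)) + b_ψ)`, which suppress irrelevant
regions of the skip feature using the coarser gating signal. Training is
two-phase transfer learning: the backbone is pretrained on a
segmentation-only pool (7:1:2 split), its encoder and bridge are copied
bit-exactly into the multi-task model, and the joint model is trained with
five-fold stratified cross-validation, horizontal-flip augmentation and
Adam (batch 16, lr 0.005 with step decay). Evaluation reports IoU/DSC,
accuracy and macro precision/recall/F1 with percentile-bootstrap 95 % CIs
(5000 resamples) and a 7×7 confusion matrix. Ablation variants (plain
U-Net backbone, no pretraining, regression head, two-stage
segment-then-classify) run through the same pipeline.

Because the curated radiograph crops are not redistributable, the package
ships a synthetic stage-graded bone generator (`drumtl.synthetic`) whose
masks carry the stage signal in their boundary morphology (gap narrowing,
medial capping, fusion); every experiment here runs end to end on it, on a
single CPU. The networks run on a small NumPy reverse-mode autodiff layer
included in the package (`drumtl.nn`) — no GPU or deep-learning framework
required.

## Worked example

```python
from drumtl import (GradeCodec, SyntheticConfig, TrainConfig,
                    generate_dataset, pretrain_backbone, train_multitask,
                    evaluate_model)

pre, mt, test = generate_dataset(SyntheticConfig(
    side=64, n_per_stage=70, n_per_stage_pretrain=100, n_per_stage_test=20,
    seed=11))
cfg = TrainConfig(side=64, base_channels=16, pretrain_epochs=2, epochs=4,
                  run_cv=False, seed=11)

backbone = pretrain_backbone(pre, cfg)
print(f"pretrained backbone: IoU {backbone.test_iou:.3f}, DSC {backbone.test_dsc:.3f}")

result = train_multitask(mt, backbone.backbone, cfg)
report = evaluate_model(result.final_model, test, GradeCodec.for_bone("radius"),
                        n_boot=500, seed=1)
acc, lo, hi = report.cls["accuracy"]
print(f"test accuracy {acc:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
      f"seg DSC {report.seg['dsc'][0]:.3f}")
```

On one CPU this prints (about five minutes):

```
pretrained backbone: IoU 0.997, DSC 0.998
test accuracy 0.750 (95% CI 0.679-0.821), seg DSC 0.999
```

i.e. the pretrained backbone segments the synthetic bone almost perfectly,
and after four epochs of joint training the grading head recovers the
7-stage signal from the shared features at 75 % accuracy (chance is
1/7 ≈ 14 %) while joint training keeps segmentation at DSC ≈ 0.999.

A command-line interface wraps the same pipeline:

```bash
drumtl generate --out data --n-per-stage 20 --side 64 --seed 1
drumtl pretrain --data data/pretrain --out runs/backbone --epochs 5 --side 64
drumtl train --data data/multitask --backbone runs/backbone/backbone.npz --out runs/mt
drumtl evaluate --model runs/mt/multitask.npz --data data/test --out runs/eval --n-boot 5000
drumtl sweep-lambda --data data/multitask --grid 0,0.2,0.4,0.6,0.8,1.0 --out runs/sweep
```

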