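"""Training objectives: Dice, cross-entropy, and the multi-task combination.

The joint objective is L_m = lambda * L_seg + (1 - lambda) * L_cla with
lambda in [0, 1]; lambda = 0.4 is the default, the weighting under which
the grading branch performs best.  L_seg is a smoothed soft Dice loss
computed on probabilities (differentiable; hard-mask Dice is an evaluation
metric, see :mod:`drumtl.evaluation`), reduced per image then averaged over
the batch.  L_cla is mean cross-entropy against one-hot stage labels.  The
regression-head variant replaces cross-entropy with mean squared error on
the integer stage index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor

__all__ = [
    "LossConfig",
    "dice_loss",
    "cross_entropy_loss",
    "combined_loss",
    "mse_stage_loss",
]

PROB_EPS = 1e-12


@dataclass(frozen=True)
class LossConfig:
    lambda_weight: float = 0.4
    smooth_theta: float = 1.0
    n_classes: int = 7

    def __post_init__(self):
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must be in [0, 1]")
        if self.smooth_theta <= 0:
            raise ValueError("smooth_theta must be positive")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def dice_loss(pred, truth, theta: float = 1.0) -> Tensor:
    """Smoothed soft Dice loss, 1 - (2 * sum(p*t) + theta) / (sum p + sum t + theta).

    Accepts a single (H, W) pair or a batch (N, 1, H, W)/(N, H, W); batches
    are reduced per image and then averaged.  ``theta`` is the smoothing
    term that keeps the ratio finite when both masks are empty.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    pred, truth = _as_tensor(pred), _as_tensor(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.ndim == 2:
        axes = (0, 1)
    else:
        axes = tuple(range(1, pred.ndim))
    inter = (pred * truth).sum(axis=axes)
    sums = pred.sum(axis=axes) + truth.sum(axis=axes)
    per_image = 1.0 - (2.0 * inter + theta) / (sums + theta)
    return per_image.mean() if pred.ndim > 2 else per_image


def cross_entropy_loss(probs, labels) -> Tensor:
    """Mean negative log-probability of the true stage.

    ``probs`` is an (n, k) row-stochastic matrix (rows sum to 1), ``labels``
    integer stage indices.  With one-hot ground truth the double sum over
    classes collapses to the true-class log term.  Probabilities are clamped
    at 1e-12 inside the log for numerical safety (a warning is emitted when
    the clamp is active).
    """
    probs = _as_tensor(probs)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or labels.ndim != 1 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probs must be (n, k) with one label per row")
    n, k = probs.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must be in [0, {k - 1}]")
    row_sums = probs.data.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    onehot = np.zeros((n, k), dtype=probs.dtype)
    onehot[np.arange(n), labels] = 1.0
    p_true = (probs * Tensor(onehot)).sum(axis=1)
    if (p_true.data < PROB_EPS).any():
        warnings.warn("true-class probability clamped at 1e-12", RuntimeWarning)
    return -(p_true.clamp_min(PROB_EPS).log().mean())


def cross_entropy_from_logits(logits, labels) -> Tensor:
    """Cross-entropy computed from unnormalised scores via log-softmax.

    Identical in value to ``cross_entropy_loss(softmax(logits), labels)``
    but immune to probability underflow, so confidently-wrong samples keep
    a usable gradient; the training loop prefers this path.
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    n, k = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant
    z = logits - shift
    log_norm = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    log_p_true = ((z - log_norm) * Tensor(onehot)).sum(axis=1)
    return -(log_p_true.mean())


def combined_loss(l_seg, l_cla, lambda_weight: float = 0.4):
    """Multi-task objective lambda * L_seg + (1 - lambda) * L_cla."""
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValueError("lambda_weight must be in [0, 1]")
    return lambda_weight * l_seg + (1.0 - lambda_weight) * l_cla


def mse_stage_loss(stage_value, labels) -> Tensor:
    """Mean squared error of the regression head against integer stages."""
    stage_value = _as_tensor(stage_value)
    diff = stage_value - Tensor(np.asarray(labels, dtype=stage_value.dtype))
    return (diff * diff).mean()
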