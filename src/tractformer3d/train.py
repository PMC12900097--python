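"""Progressive volumetric-patch training.

The network is symmetric (output resolution equals input resolution at every
accepted size), so it can be trained on small random patches and run on
whole volumes at test time. Training follows a two-stage curriculum of
growing patch sizes; the default schedule mirrors the published protocol
(patches 64^3 with batch 6, then 80^3 with batch 2; 1000 iterations per
epoch; AdamW with beta1 0.9, beta2 0.999, weight decay 1e-4; learning rate
cosine-annealed from 3e-4 to 1e-6 over the full run). The 200 total epochs
are split equally between the two stages; the split is configurable.

Patch sampling is foreground-aware: a uniformly random corner is redrawn up
to 10 times until the patch holds at least 0.1% foreground voxels, then
accepted unconditionally — unbiased in the limit while avoiding
all-background batches.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_volumes import PeakVolume, TractLabelVolume
from .model import TractFormerNet, threshold_probabilities
from .nn import AdamW, Tensor, no_grad
from .nn.functional import bce_with_logits
from .phantom import Phantom

__all__ = ["TrainingSchedule", "TrainingDivergedError", "bce_loss",
           "cosine_lr", "sample_patch", "run_training"]

FOREGROUND_FRACTION = 1e-3
MAX_RESAMPLES = 10


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass(frozen=True)
class TrainingSchedule:
    """Ordered stages of (patch_size, batch_size, epochs)."""

    stages: tuple[tuple[int, int, int], ...] = ((64, 6, 100), (80, 2, 100))
    iterations_per_epoch: int = 1000
    lr_start: float = 3e-4
    lr_end: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        sizes = [s[0] for s in self.stages]
        if sizes != sorted(sizes):
            raise ValueError("patch sizes must be nondecreasing across stages")
        if any(s[1] < 1 for s in self.stages):
            raise ValueError("batch sizes must be positive")

    @property
    def total_steps(self) -> int:
        return sum(e for _, _, e in self.stages) * self.iterations_per_epoch


def bce_loss(prob: np.ndarray, labels: np.ndarray,
             eps: float = 1e-7) -> float:
    """Mean binary cross-entropy of a probability grid against binary labels.

    (Training itself evaluates the loss from logits for stability; this is
    the probability-domain form used for reporting.)
    """
    p = np.asarray(prob, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def cosine_lr(step: int, total_steps: int, lr_start: float = 3e-4,
              lr_end: float = 1e-6) -> float:
    """Single cosine decay, no restarts: lr(0)=lr_start, lr(T)=lr_end."""
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    return lr_end + 0.5 * (lr_start - lr_end) * (
        1.0 + np.cos(np.pi * step / total_steps))


def sample_patch(peaks: PeakVolume | np.ndarray,
                 labels: TractLabelVolume | np.ndarray,
                 patch_size: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw a congruent (peak, label) patch with a uniformly random corner.

    Rejection rule: redraw up to 10 times until the label patch holds at
    least 0.1% foreground voxels; the final draw is accepted unconditionally.
    """
    pk = peaks.data if isinstance(peaks, PeakVolume) else np.asarray(peaks)
    lb = labels.data if isinstance(labels, TractLabelVolume) else np.asarray(labels)
    dims = pk.shape[:3]
    if any(patch_size > n for n in dims):
        raise ValueError(f"patch size {patch_size} exceeds volume dims {dims}")
    for _ in range(MAX_RESAMPLES + 1):
        corner = [int(rng.integers(0, n - patch_size + 1)) for n in dims]
        sl = tuple(slice(c, c + patch_size) for c in corner)
        lp = lb[sl]
        if lp.mean(dtype=np.float64) >= FOREGROUND_FRACTION:
            break
    return pk[sl].copy(), lp.copy()


def _mean_dice(net: TractFormerNet, phantoms: Sequence[Phantom]) -> float:
    from .evaluate import dice_score
    scores = []
    for ph in phantoms:
        pred = threshold_probabilities(net.predict_proba(ph.peaks),
                                       net.cfg.threshold)
        for t in range(ph.labels.n_tracts):
            scores.append(dice_score(pred[..., t], ph.labels.data[..., t]))
    return float(np.mean(scores))


@dataclass
class TrainingResult:
    net: TractFormerNet
    history: list[dict] = field(default_factory=list)
    best_val_dice: float | None = None
    checkpoint: dict | None = None


def run_training(net: TractFormerNet, phantoms: Sequence[Phantom],
                 schedule: TrainingSchedule,
                 validation: Sequence[Phantom] | None = None,
                 log_every: int = 1) -> TrainingResult:
    """Train in place; returns the net with a per-step loss history.

    Stages run in order with their own patch and batch sizes; the optimizer
    state and the cosine learning-rate schedule span the whole run. A
    non-finite loss aborts with :class:`TrainingDivergedError`. When a
    validation set is supplied, weights with the best validation Dice are
    recorded and restored at the end.
    """
    if not phantoms:
        raise ValueError("need at least one training volume")
    rng = np.random.default_rng(schedule.seed)
    opt = AdamW(net.parameters(), lr=schedule.lr_start,
                betas=(schedule.beta1, schedule.beta2),
                weight_decay=schedule.weight_decay)
    total = schedule.total_steps
    result = TrainingResult(net=net)
    if total == 0:
        return result
    step = 0
    for stage_idx, (patch, batch, epochs) in enumerate(schedule.stages):
        for epoch in range(epochs):
            for _ in range(schedule.iterations_per_epoch):
                xs, ys = [], []
                for _ in range(batch):
                    ph = phantoms[int(rng.integers(len(phantoms)))]
                    x, y = sample_patch(ph.peaks, ph.labels, patch, rng)
                    xs.append(x)
                    ys.append(y)
                xb = np.stack(xs)
                yb = np.stack(ys).astype(np.float32)
                opt.lr = cosine_lr(step, total, schedule.lr_start, schedule.lr_end)
                net.zero_grad()
                logits = net.logits(Tensor(xb))
                loss = bce_with_logits(logits, yb)
                if not np.isfinite(loss.item()):
                    raise TrainingDivergedError(
                        f"non-finite loss at step {step}")
                loss.backward()
                opt.step()
                if step % log_every == 0:
                    result.history.append({
                        "step": step, "stage": stage_idx, "epoch": epoch,
                        "patch_size": patch, "batch_size": batch,
                        "lr": opt.lr, "loss": loss.item(),
                    })
                step += 1
            if validation:
                val = _mean_dice(net, validation)
                if result.best_val_dice is None or val > result.best_val_dice:
                    result.best_val_dice = val
                    result.checkpoint = net.state_dict()
    if result.checkpoint is not None:
        net.load_state_dict(result.checkpoint)
    return result
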