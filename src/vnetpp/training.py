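"""Training loop: Nesterov-accelerated adaptive moment estimation (Nadam)
minimizing the LCFT loss, with per-epoch metric history and best-validation
checkpointing.  Defaults follow the printed configuration: learning rate
0.0002, 30 epochs, Nadam."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._autograd import Tensor
from .architecture import SegmentationModel
from .brats_io import SliceSample
from .losses import (
    LossConfig,
    dice_coefficient,
    hard_confusion_counts,
    lcft_total_loss,
)

__all__ = ["TrainingConfig", "TrainingResult", "Nadam", "train_model", "samples_to_arrays"]


@dataclass
class TrainingConfig:
    learning_rate: float = 2e-4
    optimizer: str = "nadam"
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    checkpoint_dir: Path | None = None
    #: optional hard cap on optimization steps (overrides epochs when hit)
    max_steps: int | None = None

    def __post_init__(self):
        if self.optimizer != "nadam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainingResult:
    history: list[dict]
    final_checkpoint: Path | None
    config_echo: TrainingConfig
    best_val_dice: float


class Nadam:
    """Nadam: Adam with a Nesterov momentum correction on the first moment."""

    def __init__(self, params: dict, lr: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def samples_to_arrays(samples: list[SliceSample], n_classes: int):
    """Stack slice samples into (N,C,H,W) images and (N,K,H,W) one-hot masks."""
    if not samples:
        raise ValueError("empty slice list")
    x = np.stack([s.image for s in samples]).transpose(0, 3, 1, 2).astype(np.float64)
    masks = np.stack([s.mask for s in samples])
    if masks.max() >= n_classes:
        raise ValueError("mask label exceeds n_classes")
    onehot = np.eye(n_classes)[masks].transpose(0, 3, 1, 2)
    return x, onehot, masks


def _mean_foreground_dice(model: SegmentationModel, x, masks, n_classes, batch_size):
    """Pooled hard foreground Dice + argmax accuracy over a dataset."""
    preds = []
    for i in range(0, x.shape[0], batch_size):
        out = model.forward(Tensor(x[i : i + batch_size]), train=False)
        preds.append(out.data.argmax(axis=1))
    pred = np.concatenate(preds)
    counts = hard_confusion_counts(pred, masks, n_classes)
    return float(np.mean(dice_coefficient(counts)[1:]))


def _dataset_loss(model, x, onehot, loss_config, batch_size):
    losses, weights = [], []
    for i in range(0, x.shape[0], batch_size):
        out = model.forward(Tensor(x[i : i + batch_size]), train=False)
        loss = lcft_total_loss(out.data, onehot[i : i + batch_size], loss_config,
                               class_axis=1)
        losses.append(float(loss))
        weights.append(out.shape[0])
    return float(np.average(losses, weights=weights))


def train_model(
    model: SegmentationModel,
    train_data: list[SliceSample],
    val_data: list[SliceSample] | None,
    config: TrainingConfig,
) -> TrainingResult:
    """Optimize the model on slice samples; returns the per-epoch history."""
    if not train_data:
        raise ValueError("train_data is empty")
    nc = model.spec.n_classes
    x_tr, y_tr, m_tr = samples_to_arrays(train_data, nc)
    if val_data:
        x_va, y_va, m_va = samples_to_arrays(val_data, nc)
    rng = np.random.default_rng(config.seed)
    opt = Nadam(model.parameters(), lr=config.learning_rate)
    history: list[dict] = []
    best_val = -np.inf
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    best_path = final_path = None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        best_path = ckpt_dir / "best.npz"
        final_path = ckpt_dir / "final.npz"

    steps = 0
    for epoch in range(config.epochs):
        order = rng.permutation(x_tr.shape[0])
        epoch_losses = []
        epoch_counts = None
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            out = model.forward(Tensor(x_tr[idx]), train=True)
            loss = lcft_total_loss(out, Tensor(y_tr[idx]), config.loss, class_axis=1)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {steps}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            # training dice pooled from the training-mode forward passes
            bc = hard_confusion_counts(out.data.argmax(axis=1), m_tr[idx], nc)
            if epoch_counts is None:
                epoch_counts = bc
            else:
                epoch_counts = type(bc)(
                    tp=epoch_counts.tp + bc.tp, fp=epoch_counts.fp + bc.fp,
                    fn=epoch_counts.fn + bc.fn, tn=epoch_counts.tn + bc.tn,
                    n_classes=nc,
                )
            steps += 1
            if config.max_steps is not None and steps >= config.max_steps:
                break
        record = {
            "epoch": epoch,
            "steps": steps,
            "train_loss": float(np.mean(epoch_losses)),
            "train_dice": float(np.mean(dice_coefficient(epoch_counts)[1:])),
        }
        if val_data:
            record["val_loss"] = _dataset_loss(model, x_va, y_va, config.loss,
                                               config.batch_size)
            record["val_dice"] = _mean_foreground_dice(model, x_va, m_va, nc,
                                                       config.batch_size)
            if record["val_dice"] > best_val:
                best_val = record["val_dice"]
                if best_path:
                    model.save(best_path)
        history.append(record)
        if config.max_steps is not None and steps >= config.max_steps:
            break
    if final_path:
        model.save(final_path)
    if not val_data:
        best_val = history[-1]["train_dice"]
        if best_path:
            model.save(best_path)
    return TrainingResult(
        history=history,
        final_checkpoint=final_path,
        config_echo=replace(config),
        best_val_dice=float(best_val),
    )
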