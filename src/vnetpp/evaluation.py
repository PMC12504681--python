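"""Evaluation reports, the six-variant ablation harness, one-way ANOVA and
qualitative montages.

Reported overlap metrics use hard argmax predictions pooled into one global
confusion table (macro over foreground classes by default); the loss column
uses the soft differentiable definition, matching how training sees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from ._autograd import Tensor
from .architecture import VARIANT_NAMES, SegmentationModel, build_variant
from .brats_io import SliceSample
from .losses import (
    LossConfig,
    dice_coefficient,
    hard_confusion_counts,
    jaccard_index,
    lcft_total_loss,
    tversky_index,
)
from .training import TrainingConfig, samples_to_arrays, train_model

__all__ = [
    "MetricsReport",
    "AblationReport",
    "evaluate_model",
    "run_ablation",
    "one_way_anova",
    "render_montage",
]

_COLUMNS = ("loss", "dice", "jaccard", "tversky", "accuracy")


@dataclass
class MetricsReport:
    """The five report columns plus per-class and whole-tumor breakdowns."""

    loss: float
    dice: float
    jaccard: float
    tversky: float
    accuracy: float
    per_class: dict[str, list[float]] = field(default_factory=dict)
    whole_tumor: dict[str, float] = field(default_factory=dict)
    n_samples: int = 0

    def __post_init__(self):
        if self.jaccard > self.dice + 1e-12:
            raise ValueError("invariant violated: jaccard must not exceed dice")
        for name in ("dice", "jaccard", "tversky", "accuracy"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def row(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in _COLUMNS}


@dataclass
class AblationReport:
    rows: dict[str, MetricsReport]
    scale: str

    def __post_init__(self):
        if set(self.rows) != set(VARIANT_NAMES):
            raise ValueError(f"ablation requires exactly the rows {VARIANT_NAMES}")

    def to_tsv(self) -> str:
        lines = ["variant\t" + "\t".join(_COLUMNS)]
        for name in VARIANT_NAMES:
            r = self.rows[name].row()
            lines.append(name + "\t" + "\t".join(f"{r[c]:.6f}" for c in _COLUMNS))
        return "\n".join(lines) + "\n"


def evaluate_model(
    model: SegmentationModel,
    data: list[SliceSample],
    loss_config: LossConfig | None = None,
    batch_size: int = 8,
    per_slice: bool = False,
) -> MetricsReport:
    """Pooled hard-count metrics + soft loss over a slice dataset.

    ``per_slice=True`` averages metrics over slices instead of pooling one
    global confusion table.
    """
    if not data:
        raise ValueError("empty evaluation dataset")
    loss_config = loss_config or LossConfig()
    nc = model.spec.n_classes
    x, onehot, masks = samples_to_arrays(data, nc)
    preds = []
    losses, weights = [], []
    for i in range(0, x.shape[0], batch_size):
        out = model.forward(Tensor(x[i : i + batch_size]), train=False)
        preds.append(out.data.argmax(axis=1))
        losses.append(float(lcft_total_loss(out.data, onehot[i : i + batch_size],
                                            loss_config, class_axis=1)))
        weights.append(out.shape[0])
    pred = np.concatenate(preds)
    loss = float(np.average(losses, weights=weights))

    def metrics_from(pred_labels, true_labels):
        counts = hard_confusion_counts(pred_labels, true_labels, nc)
        dice = dice_coefficient(counts)
        jac = jaccard_index(counts)
        tv = tversky_index(counts, loss_config.tversky)
        acc = counts.tp.sum() / counts.total_pixels[0]
        return counts, dice, jac, tv, float(acc)

    if per_slice:
        per = [metrics_from(pred[i], masks[i]) for i in range(pred.shape[0])]
        dice = np.mean([np.mean(m[1][1:]) for m in per])
        jac = np.mean([np.mean(m[2][1:]) for m in per])
        tv = np.mean([np.mean(m[3][1:]) for m in per])
        acc = float(np.mean([m[4] for m in per]))
        counts = metrics_from(pred, masks)[0]
    else:
        counts, dice_pc, jac_pc, tv_pc, acc = metrics_from(pred, masks)
        dice = float(np.mean(dice_pc[1:]))
        jac = float(np.mean(jac_pc[1:]))
        tv = float(np.mean(tv_pc[1:]))

    dice_pc = dice_coefficient(counts)
    jac_pc = jaccard_index(counts)
    tv_pc = tversky_index(counts, loss_config.tversky)
    wt_counts = hard_confusion_counts((pred > 0).astype(int), (masks > 0).astype(int), 2)
    whole_tumor = {
        "dice": float(dice_coefficient(wt_counts)[1]),
        "jaccard": float(jaccard_index(wt_counts)[1]),
        "tversky": float(tversky_index(wt_counts, loss_config.tversky)[1]),
    }
    return MetricsReport(
        loss=loss,
        dice=float(dice),
        jaccard=float(jac),
        tversky=float(tv),
        accuracy=float(acc),
        per_class={
            "dice": [float(v) for v in dice_pc],
            "jaccard": [float(v) for v in jac_pc],
            "tversky": [float(v) for v in tv_pc],
        },
        whole_tumor=whole_tumor,
        n_samples=len(data),
    )


def run_ablation(
    data: list[SliceSample],
    scale: str = "test",
    base_config: TrainingConfig | None = None,
    train_fraction: float = 0.8,
) -> AblationReport:
    """Train and evaluate all six ablation variants on identical data/seed.

    Slices are split deterministically (by base_config.seed) into train/test;
    every variant sees identical orderings because each training run re-seeds
    from the shared config.
    """
    base_config = base_config or TrainingConfig()
    if len(data) < 2:
        raise ValueError("need at least 2 slices for the ablation split")
    rng = np.random.default_rng(base_config.seed)
    order = rng.permutation(len(data))
    n_train = max(1, min(len(data) - 1, int(round(train_fraction * len(data)))))
    train = [data[i] for i in order[:n_train]]
    test = [data[i] for i in order[n_train:]]

    rows: dict[str, MetricsReport] = {}
    for name in VARIANT_NAMES:
        model, loss_config = build_variant(name, scale=scale, seed=base_config.seed)
        cfg = replace(base_config, loss=loss_config)
        train_model(model, train, None, cfg)
        rows[name] = evaluate_model(model, test, loss_config,
                                    batch_size=base_config.batch_size)
    return AblationReport(rows=rows, scale=scale)


def one_way_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and upper-tail p value.

    Between/within mean-square ratio with (k-1, N-k) degrees of freedom.
    Zero within-group variance with unequal means yields (inf, 0.0).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least 1 value")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total - k < 1:
        raise ValueError("need at least one group with >= 2 values")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        if ms_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return float(f_stat), p


#: label colors shared by every montage panel (background, core, edema, enhancing)
_LABEL_COLORS = ("black", "tab:red", "tab:green", "tab:blue")


def render_montage(sample: SliceSample, prediction: np.ndarray, out_path: Path,
                   channel: int = 3) -> Path:
    """Side-by-side input / ground truth / prediction panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    prediction = np.asarray(prediction)
    if sample.mask is None:
        raise ValueError("montage requires a sample with a ground-truth mask")
    if prediction.shape != sample.mask.shape:
        raise ValueError(
            f"prediction shape {prediction.shape} != mask shape {sample.mask.shape}"
        )
    cmap = ListedColormap(_LABEL_COLORS)
    norm = BoundaryNorm(np.arange(-0.5, len(_LABEL_COLORS)), cmap.N)
    fig = plt.figure(figsize=(9, 3.2))
    panels = (
        (sample.image[:, :, channel], "input", dict(cmap="gray")),
        (sample.mask, "ground truth", dict(cmap=cmap, norm=norm, interpolation="nearest")),
        (prediction, "prediction", dict(cmap=cmap, norm=norm, interpolation="nearest")),
    )
    for i, (img, title, kw) in enumerate(panels):
        # fixed panel geometry (a third of the figure each, title strip on top)
        ax = fig.add_axes((i / 3 + 0.01, 0.02, 1 / 3 - 0.02, 0.86))
        ax.imshow(img, **kw)
        ax.set_title(title)
        ax.axis("off")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
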