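"""Overlap metrics and the composite Log-Cosh-Focal-Tversky (LCFT) loss.

Every metric and loss is a function of per-class confusion *mass*
(:class:`PerClassCounts`).  During training the counts are soft
(tp = sum of p*g over pixels) so the whole loss is differentiable; at
evaluation time the same formulas run on hard integer counts from argmax
predictions.  Functions accept either NumPy arrays or autodiff Tensors.

Metrics:

* Dice          2*TP / (2*TP + FN + FP)
* Jaccard       TP / (TP + FP + FN)
* Tversky       TP / (TP + a*FN + b*FP)      (a=b=0.5 -> Dice; a=b=1 -> Jaccard)

Loss components:

* Log-Cosh Dice    log(cosh(1 - Dice))
* Focal Tversky    (1 - Tversky)^gamma
* Jaccard loss     1 - Jaccard

Total loss: w_lc * L_LCDice + w_ft * L_FocalTversky + w_j * L_Jaccard with
default weights 0.6 / 0.2 / 0.2 and gamma = 0.75; the weights sum to 1 so
the total stays below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, logcosh

__all__ = [
    "PerClassCounts",
    "TverskyParams",
    "LossConfig",
    "soft_confusion_counts",
    "hard_confusion_counts",
    "dice_coefficient",
    "jaccard_index",
    "tversky_index",
    "log_cosh_dice_loss",
    "focal_tversky_loss",
    "jaccard_loss",
    "lcft_loss_from_counts",
    "lcft_total_loss",
]

DEFAULT_SMOOTH = 1e-6


@dataclass
class PerClassCounts:
    """Per-class confusion mass (soft or hard) over a set of pixels.

    Invariants for valid inputs: every entry is nonnegative, ``tp + fn``
    equals the ground-truth mass of the class, and ``tp + fp + fn + tn``
    equals the total pixel count, per class.
    """

    tp: object
    fp: object
    fn: object
    tn: object
    n_classes: int

    def __post_init__(self):
        if isinstance(self.tp, Tensor):
            return
        self.tp = np.asarray(self.tp, dtype=np.float64)
        self.fp = np.asarray(self.fp, dtype=np.float64)
        self.fn = np.asarray(self.fn, dtype=np.float64)
        self.tn = np.asarray(self.tn, dtype=np.float64)
        for name in ("tp", "fp", "fn", "tn"):
            arr = getattr(self, name)
            if arr.shape != (self.n_classes,):
                raise ValueError(f"{name} must have shape ({self.n_classes},), got {arr.shape}")
            if np.any(arr < -1e-9):
                raise ValueError(f"{name} contains negative mass")

    @property
    def total_pixels(self) -> np.ndarray:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class TverskyParams:
    """Asymmetric FN/FP weights; alpha_tv > beta_tv penalizes missed tumor more."""

    alpha_tv: float = 0.7
    beta_tv: float = 0.3

    def __post_init__(self):
        if self.alpha_tv < 0 or self.beta_tv < 0:
            raise ValueError("Tversky weights must be nonnegative")


#: allowed class-aggregation modes for scalar losses
AGGREGATIONS = ("macro_all", "macro_foreground")


@dataclass
class LossConfig:
    w_lc: float = 0.6
    w_ft: float = 0.2
    w_j: float = 0.2
    focal_gamma: float = 0.75
    tversky: TverskyParams = field(default_factory=TverskyParams)
    smooth: float = DEFAULT_SMOOTH
    class_aggregation: str = "macro_all"
    #: "lcft" for the composite loss; "dice" for the plain Dice-loss baselines
    kind: str = "lcft"

    def __post_init__(self):
        if self.kind not in ("lcft", "dice"):
            raise ValueError(f"loss kind must be 'lcft' or 'dice', got {self.kind!r}")
        if abs(self.w_lc + self.w_ft + self.w_j - 1.0) > 1e-9:
            raise ValueError(
                f"loss weights must sum to 1, got {self.w_lc + self.w_ft + self.w_j}"
            )
        if self.focal_gamma <= 0:
            raise ValueError("focal_gamma must be positive")
        if self.smooth < 0:
            raise ValueError("smooth must be nonnegative")
        if self.class_aggregation not in AGGREGATIONS:
            raise ValueError(f"class_aggregation must be one of {AGGREGATIONS}")


# ---------------------------------------------------------------------------
# confusion counts
# ---------------------------------------------------------------------------


def soft_confusion_counts(
    probs, truth, validate: bool = True, class_axis: int = -1
) -> PerClassCounts:
    """Differentiable confusion mass from probability and one-hot maps.

    Both inputs share one shape, with classes along ``class_axis``.
    Per class c: tp = sum p_c*g_c, fp = sum p_c*(1-g_c), fn = sum (1-p_c)*g_c,
    tn = pixels - tp - fp - fn.
    """
    is_tensor = isinstance(probs, Tensor) or isinstance(truth, Tensor)
    if not is_tensor:
        probs = np.asarray(probs, dtype=np.float64)
        truth = np.asarray(truth, dtype=np.float64)
        if probs.shape != truth.shape:
            raise ValueError(f"shape mismatch: probs {probs.shape} vs truth {truth.shape}")
        if validate:
            if np.any(probs < -1e-9) or np.any(probs > 1 + 1e-9):
                raise ValueError("probabilities outside [0, 1]")
            if not np.allclose(probs.sum(axis=class_axis), 1.0, atol=1e-5):
                raise ValueError("probabilities do not sum to 1 per pixel")
            if np.any((truth != 0) & (truth != 1)):
                raise ValueError("truth must be one-hot")
            if not np.allclose(truth.sum(axis=class_axis), 1.0):
                raise ValueError("truth must be one-hot (rows summing to 1)")
    class_axis = class_axis % probs.ndim
    n_classes = probs.shape[class_axis]
    axes = tuple(i for i in range(probs.ndim) if i != class_axis)
    n_pixels = float(np.prod(probs.shape)) / n_classes
    tp = (probs * truth).sum(axis=axes)
    fp = (probs * (1.0 - truth)).sum(axis=axes)
    fn = ((1.0 - probs) * truth).sum(axis=axes)
    tn = n_pixels - tp - fp - fn
    return PerClassCounts(tp=tp, fp=fp, fn=fn, tn=tn, n_classes=int(n_classes))


def hard_confusion_counts(pred_labels, true_labels, n_classes: int) -> PerClassCounts:
    """Integer confusion counts from label maps (argmax predictions)."""
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction/truth shape mismatch")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (true, pred), 1)
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = pred.size - tp - fp - fn
    return PerClassCounts(tp=tp, fp=fp, fn=fn, tn=tn, n_classes=n_classes)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def dice_coefficient(counts: PerClassCounts, smooth: float = DEFAULT_SMOOTH):
    return (2.0 * counts.tp + smooth) / (2.0 * counts.tp + counts.fn + counts.fp + smooth)


def jaccard_index(counts: PerClassCounts, smooth: float = DEFAULT_SMOOTH):
    return (counts.tp + smooth) / (counts.tp + counts.fp + counts.fn + smooth)


def tversky_index(
    counts: PerClassCounts,
    params: TverskyParams | None = None,
    smooth: float = DEFAULT_SMOOTH,
):
    params = params or TverskyParams()
    return (counts.tp + smooth) / (
        counts.tp + params.alpha_tv * counts.fn + params.beta_tv * counts.fp + smooth
    )


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------


def log_cosh_dice_loss(counts: PerClassCounts, smooth: float = DEFAULT_SMOOTH):
    return logcosh(1.0 - dice_coefficient(counts, smooth))


def focal_tversky_loss(
    counts: PerClassCounts,
    params: TverskyParams | None = None,
    focal_gamma: float = 0.75,
    smooth: float = DEFAULT_SMOOTH,
):
    if focal_gamma <= 0:
        raise ValueError("focal_gamma must be positive")
    return (1.0 - tversky_index(counts, params, smooth)) ** focal_gamma


def jaccard_loss(counts: PerClassCounts, smooth: float = DEFAULT_SMOOTH):
    return 1.0 - jaccard_index(counts, smooth)


def _aggregate(per_class, mode: str):
    if mode == "macro_all":
        return per_class.mean()
    if mode == "macro_foreground":
        return per_class[1:].mean()
    raise ValueError(f"unknown aggregation {mode!r}")


def lcft_loss_from_counts(counts: PerClassCounts, config: LossConfig | None = None):
    """Weighted LCFT loss evaluated on a confusion table, aggregated per config."""
    config = config or LossConfig()
    if config.kind == "dice":
        return _aggregate(1.0 - dice_coefficient(counts, config.smooth),
                          config.class_aggregation)
    lc = _aggregate(log_cosh_dice_loss(counts, config.smooth), config.class_aggregation)
    ft = _aggregate(
        focal_tversky_loss(counts, config.tversky, config.focal_gamma, config.smooth),
        config.class_aggregation,
    )
    jl = _aggregate(jaccard_loss(counts, config.smooth), config.class_aggregation)
    return config.w_lc * lc + config.w_ft * ft + config.w_j * jl


def lcft_total_loss(probs, truth, config: LossConfig | None = None, class_axis: int = -1):
    """Total training loss from probability and one-hot maps."""
    config = config or LossConfig()
    counts = soft_confusion_counts(probs, truth, class_axis=class_axis)
    return lcft_loss_from_counts(counts, config)
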