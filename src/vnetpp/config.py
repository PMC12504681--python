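"""YAML run configuration: one file covering data, architecture, loss,
training and evaluation settings, validated strictly (unknown keys rejected).
All defaults are the printed pipeline values."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .architecture import ArchitectureSpec
from .losses import LossConfig, TverskyParams
from .training import TrainingConfig

__all__ = ["DataConfig", "EvaluationConfig", "RunConfig", "load_config", "default_config_yaml"]


@dataclass
class DataConfig:
    data_dir: str | None = None
    slice_window: tuple[int, int] = (30, 120)
    crop_to: int = 192
    train_fraction: float = 0.8
    split_seed: int = 0
    #: split at patient level by default; "slice" splits pooled slices
    split_level: str = "patient"

    def __post_init__(self):
        if self.split_level not in ("patient", "slice"):
            raise ValueError("split_level must be 'patient' or 'slice'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class EvaluationConfig:
    per_slice: bool = False
    batch_size: int = 8


@dataclass
class RunConfig:
    data: DataConfig = field(default_factory=DataConfig)
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)


_SECTIONS = {
    "data": DataConfig,
    "architecture": ArchitectureSpec,
    "loss": LossConfig,
    "training": TrainingConfig,
    "evaluation": EvaluationConfig,
}


def _build_section(cls, raw: dict):
    if not isinstance(raw, dict):
        raise ValueError(f"section for {cls.__name__} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(raw)
    # nested structures
    if cls is LossConfig and "tversky" in kwargs and isinstance(kwargs["tversky"], dict):
        kwargs["tversky"] = TverskyParams(**kwargs["tversky"])
    if cls is TrainingConfig and "loss" in kwargs and isinstance(kwargs["loss"], dict):
        kwargs["loss"] = _build_section(LossConfig, kwargs["loss"])
    for key in ("slice_window",):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    sections = {}
    for name, cls in _SECTIONS.items():
        sections[name] = _build_section(cls, raw.get(name, {}))
    cfg = RunConfig(**sections)
    # the training loop consumes the loss section
    cfg.training.loss = cfg.loss
    return cfg


def default_config_yaml() -> str:
    """A commented default config encoding the pipeline's standard values."""
    return """\
# vnetpp run configuration (all values are the pipeline defaults)
data:
  data_dir: null          # directory of case subdirectories
  slice_window: [30, 120] # half-open axial window -> 90 slices/case
  crop_to: 192            # 240 -> 192 centered edge crop
  train_fraction: 0.8     # 80/20 split
  split_seed: 0
  split_level: patient

architecture:
  n_stages: 4
  convs_per_stage: [1, 2, 3, 3]
  filters_per_stage: [16, 32, 64, 128]
  cbf_enabled: true
  cbf_filters: 500        # context-boosting convolution width
  cbf_out_channels: 256
  kernel_size: 3
  in_channels: 4          # t1, t1ce, t2, flair
  n_classes: 4
  dropout_rate: 0.1
  input_side: 192

loss:
  w_lc: 0.6               # log-cosh Dice weight
  w_ft: 0.2               # focal Tversky weight
  w_j: 0.2                # Jaccard weight
  focal_gamma: 0.75
  tversky: {alpha_tv: 0.7, beta_tv: 0.3}
  smooth: 1.0e-6
  class_aggregation: macro_all
  kind: lcft

training:
  learning_rate: 0.0002
  optimizer: nadam
  epochs: 30
  batch_size: 8
  seed: 0

evaluation:
  per_slice: false
  batch_size: 8
"""
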