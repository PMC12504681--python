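"""4-stage 2D V-Net++ encoder-decoder with a context-boosting bottleneck.

Encoder stages apply a fixed number of 3x3 convolutions (1/2/3/3 by default),
add the stage input element-wise (1x1 projection when channel counts differ),
and forward the sum both down the network (2x2 stride-2 convolution) and to
the matching decoder stage.  The deepest features pass through the
context-boosting block (2x2 max-pool -> wide convolution, 500 filters by
default -> learned x2 transpose-convolution upsampling).  Each decoder stage
upsamples with a transpose convolution, concatenates the encoder skip (so its
channel depth is twice the encoder counterpart), applies the mirrored number
of stride-1 transpose convolutions with a residual sum, and a 1x1 convolution
plus per-pixel softmax produces the class probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Tensor, concat, dropout, maxpool2d, softmax
from .layers import Conv2D, ConvTranspose2D, Module, PReLU

__all__ = [
    "ArchitectureSpec",
    "SegmentationModel",
    "CBFBlock",
    "VARIANT_NAMES",
    "build_cbf_block",
    "build_segmentation_model",
    "build_variant",
    "count_trainable_parameters",
]


@dataclass
class ArchitectureSpec:
    """Complete structural description of a segmentation network."""

    n_stages: int = 4
    convs_per_stage: list[int] = field(default_factory=lambda: [1, 2, 3, 3])
    filters_per_stage: list[int] = field(default_factory=lambda: [16, 32, 64, 128])
    cbf_filters: int = 500
    cbf_enabled: bool = True
    cbf_out_channels: int = 256
    kernel_size: int = 3
    in_channels: int = 4
    n_classes: int = 4
    dropout_rate: float = 0.1
    input_side: int = 192

    def __post_init__(self):
        if len(self.convs_per_stage) != self.n_stages:
            raise ValueError("convs_per_stage length must equal n_stages")
        if len(self.filters_per_stage) != self.n_stages:
            raise ValueError("filters_per_stage length must equal n_stages")
        if self.input_side % (2**self.n_stages) != 0:
            raise ValueError(
                f"input_side {self.input_side} must be divisible by 2^{self.n_stages}"
            )
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.filters_per_stage) < 1 or self.cbf_filters < 1:
            raise ValueError("filter counts must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        return cls(**json.loads(text))


class CBFBlock(Module):
    """Context boosting block: max-pool, wide convolution, x2 upsampling.

    The pooling halves the spatial grid before the wide (default 500-filter)
    convolution; a 2x2 stride-2 transpose convolution restores the input
    spatial size at ``out_channels`` depth so the decoder contract does not
    depend on the block being present.
    """

    def __init__(self, in_channels: int, cbf_filters: int, out_channels: int,
                 rng: np.random.Generator, kernel_size: int = 3):
        if in_channels < 1 or cbf_filters < 1:
            raise ValueError("channel counts must be positive")
        self.conv = Conv2D(in_channels, cbf_filters, kernel_size, rng)
        self.act = PReLU(cbf_filters)
        self.up = ConvTranspose2D(cbf_filters, out_channels, 2, rng, stride=2)
        self.last_hidden_shape: tuple[int, ...] | None = None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.act(self.conv(maxpool2d(x, 2)))
        self.last_hidden_shape = h.shape
        return self.up(h)


class _EncoderStage(Module):
    def __init__(self, in_ch: int, out_ch: int, n_convs: int, kernel: int,
                 rng: np.random.Generator):
        self.convs = [Conv2D(in_ch if i == 0 else out_ch, out_ch, kernel, rng)
                      for i in range(n_convs)]
        self.acts = [PReLU(out_ch) for _ in range(n_convs)]
        self.project = Conv2D(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act(conv(h))
        res = x if self.project is None else self.project(x)
        return h + res


class _DecoderStage(Module):
    """Mirrors an encoder stage with stride-1 transpose convolutions."""

    def __init__(self, channels: int, n_convs: int, kernel: int, rng: np.random.Generator):
        self.convs = [ConvTranspose2D(channels, channels, kernel, rng)
                      for _ in range(n_convs)]
        self.acts = [PReLU(channels) for _ in range(n_convs)]

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act(conv(h))
        return h + x


class SegmentationModel(Module):
    """Callable mapping (B, side, side, in_channels) images to per-pixel
    class probabilities of shape (B, side, side, n_classes)."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        n = spec.n_stages
        f = spec.filters_per_stage
        k = spec.kernel_size
        self.enc_stages = [
            _EncoderStage(spec.in_channels if i == 0 else f[i], f[i],
                          spec.convs_per_stage[i], k, rng)
            for i in range(n)
        ]
        self.down = [Conv2D(f[i], f[i + 1], 2, rng, stride=2) for i in range(n - 1)]
        if spec.cbf_enabled:
            self.cbf = CBFBlock(f[-1], spec.cbf_filters, spec.cbf_out_channels, rng, k)
            bottom_ch = spec.cbf_out_channels
        else:
            self.cbf = None
            bottom_ch = f[-1]
        self.up = []
        self.dec_stages = []
        prev = bottom_ch
        for i in range(n - 2, -1, -1):
            self.up.append(ConvTranspose2D(prev, f[i], 2, rng, stride=2))
            self.dec_stages.append(_DecoderStage(2 * f[i], spec.convs_per_stage[i], k, rng))
            prev = 2 * f[i]
        self.head = Conv2D(prev, spec.n_classes, 1, rng)
        self._dropout_rng = np.random.default_rng(rng.integers(2**63))

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        """Forward pass in NCHW; returns per-pixel class probabilities."""
        n = self.spec.n_stages
        skips = []
        h = x
        for i in range(n):
            h = self.enc_stages[i](h)
            h = dropout(h, self.spec.dropout_rate, self._dropout_rng, train)
            skips.append(h)
            if i < n - 1:
                h = self.down[i](h)
        if self.cbf is not None:
            h = self.cbf(h)
        for j, i in enumerate(range(n - 2, -1, -1)):
            h = self.up[j](h)
            h = concat([h, skips[i]], axis=1)
            h = self.dec_stages[j](h)
        return softmax(self.head(h), axis=1)

    def __call__(self, images: np.ndarray) -> np.ndarray:
        """Inference on a (B, side, side, in_channels) batch; channel-last."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"expected (B, H, W, {self.spec.in_channels}) input, got {images.shape}"
            )
        x = Tensor(images.transpose(0, 3, 1, 2))
        out = self.forward(x, train=False)
        return out.data.transpose(0, 2, 3, 1)

    # -- checkpointing ------------------------------------------------------
    def save(self, path) -> None:
        """Write weights (.npz) with the architecture spec alongside (.json)."""
        import pathlib

        path = pathlib.Path(path)
        np.savez(path, **self.state_dict())
        path.with_suffix(".json").write_text(self.spec.to_json())

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        import pathlib

        path = pathlib.Path(path)
        spec = ArchitectureSpec.from_json(path.with_suffix(".json").read_text())
        model = cls(spec, np.random.default_rng(0))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
            model.load_state_dict(dict(f))
        return model


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_cbf_block(in_channels: int, cbf_filters: int, out_channels: int = 256,
                    seed: int = 0) -> CBFBlock:
    return CBFBlock(in_channels, cbf_filters, out_channels, np.random.default_rng(seed))


def build_segmentation_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> SegmentationModel:
    return SegmentationModel(spec or ArchitectureSpec(), np.random.default_rng(seed))


def count_trainable_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters().values()))


# ---------------------------------------------------------------------------
# ablation variants
# ---------------------------------------------------------------------------

#: the six ablation rows: stage count x loss x context-boosting block
VARIANT_NAMES = (
    "baseline_vnet5_dice",
    "vnet5_lcft",
    "vnet5_cbf_dice",
    "vnet4_lcft",
    "vnet5_lcft_cbf",
    "proposed_vnet4_lcft_cbf",
)

_VARIANT_TABLE = {
    # name: (n_stages, cbf_enabled, loss_kind)
    "baseline_vnet5_dice": (5, False, "dice"),
    "vnet5_lcft": (5, False, "lcft"),
    "vnet5_cbf_dice": (5, True, "dice"),
    "vnet4_lcft": (4, False, "lcft"),
    "vnet5_lcft_cbf": (5, True, "lcft"),
    "proposed_vnet4_lcft_cbf": (4, True, "lcft"),
}


def variant_spec(name: str, scale: str = "paper") -> ArchitectureSpec:
    """Architecture spec for one ablation row at paper or test scale."""
    if name not in _VARIANT_TABLE:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
    if scale not in ("paper", "test"):
        raise ValueError(f"scale must be 'paper' or 'test', got {scale!r}")
    n_stages, cbf_enabled, _ = _VARIANT_TABLE[name]
    if scale == "paper":
        filters = [16, 32, 64, 128, 256][:n_stages]
        cbf_filters, cbf_out, side = 500, 256, 192
    else:
        filters = [4, 8, 16, 32, 64][:n_stages]
        cbf_filters, cbf_out, side = 50, 64, 64
    convs = [1, 2, 3, 3, 3][:n_stages]
    return ArchitectureSpec(
        n_stages=n_stages,
        convs_per_stage=convs,
        filters_per_stage=filters,
        cbf_filters=cbf_filters,
        cbf_enabled=cbf_enabled,
        cbf_out_channels=cbf_out,
        input_side=side,
    )


def build_variant(name: str, scale: str = "paper", seed: int = 0):
    """Build one ablation row; returns (SegmentationModel, LossConfig)."""
    from .losses import LossConfig

    spec = variant_spec(name, scale)
    _, _, loss_kind = _VARIANT_TABLE[name]
    model = build_segmentation_model(spec, seed=seed)
    return model, LossConfig(kind=loss_kind)
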