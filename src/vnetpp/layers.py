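"""Parameterized layers on top of the autodiff engine (NCHW layout)."""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, conv2d, conv_transpose2d, prelu

__all__ = ["Parameter", "Module", "Conv2D", "ConvTranspose2D", "PReLU"]


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursively collects named parameters for optimizers and I/O."""

    trainable: bool = True

    def parameters(self) -> dict[str, Parameter]:
        params: dict[str, Parameter] = {}
        if not self.trainable:
            return params
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                params[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _fan_in_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    # variance-scaling (He) fan-in initialization
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        if pad is None:
            pad = kernel // 2 if stride == 1 else 0
        self.stride = stride
        self.pad = pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_fan_in_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2D(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        if pad is None:
            pad = kernel // 2 if stride == 1 else 0
        self.stride = stride
        self.pad = pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_fan_in_init(rng, (in_ch, out_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        self.alpha = Parameter(np.full(channels, init))

    def __call__(self, x: Tensor) -> Tensor:
        return prelu(x, self.alpha, channel_axis=1)
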