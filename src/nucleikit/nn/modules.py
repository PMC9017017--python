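"""Layer modules over the autograd engine.

Modules hold :class:`Parameter` leaves and child modules, mirror the familiar
``forward`` / ``parameters`` / ``train`` / ``eval`` surface, and initialise
weights from an explicit :class:`numpy.random.Generator` so that two builds
from the same seed are bit-identical.
"""
from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """Trainable tensor; freezing is expressed by ``requires_grad=False``."""

    def __init__(self, data, requires_grad: bool = True):
        super().__init__(data, requires_grad=requires_grad)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        """Unique parameter leaves (weight sharing deduplicated by identity)."""
        seen: dict[int, Parameter] = {}
        for _, p in self.named_parameters():
            seen.setdefault(id(p), p)
        return list(seen.values())

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    @property
    def trainable_parameter_count(self) -> int:
        return sum(p.size for p in self.parameters() if p.requires_grad)

    def state_arrays(self) -> list[np.ndarray]:
        """Parameter data arrays, for snapshot/compare in determinism checks."""
        return [p.data for p in self.parameters()]


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.layers:
            x = m(x)
        return x


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """Same-padded stride-1 convolution, NHWC, odd kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.in_channels, self.out_channels, self.kernel_size = in_channels, out_channels, k
        self.weight = Parameter(_he_normal(rng, (k, k, in_channels, out_channels),
                                           k * k * in_channels))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class DepthwiseConv2d(Module):
    """Per-channel same-padded convolution (no bias)."""

    def __init__(self, channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.weight = Parameter(_he_normal(rng, (kernel_size, kernel_size, channels),
                                           kernel_size * kernel_size))

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight)


class ConvTranspose2x2(Module):
    """Stride-2 transposed convolution: exact spatial doubling."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_normal(rng, (2, 2, in_channels, out_channels),
                                           4 * in_channels))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum,
                             self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_normal(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.max_pool2x2(x)


class AvgPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.avg_pool2x2(x)


class UpsampleNearest2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample2x_nearest(x)
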