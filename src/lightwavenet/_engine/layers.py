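"""Module system: parameter containers with torch-like ergonomics."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from ..errors import ConfigError, DimensionError
from . import autograd as F
from .autograd import Parameter, Tensor


class Module:
    """Base class for layers; auto-registers Parameters and sub-Modules."""

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: p for name, p in self.named_parameters()}
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        unexpected = set(state) - (set(own) | set(bufs))
        if missing or unexpected:
            raise ConfigError(
                f"state dict mismatch: missing={sorted(missing)} "
                f"unexpected={sorted(unexpected)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise DimensionError(
                    f"parameter {name}: checkpoint shape {arr.shape} != {p.data.shape}"
                )
            p.data = arr.copy()
        for name, b in bufs.items():
            arr = np.asarray(state[name], dtype=b.dtype)
            if arr.shape != b.shape:
                raise DimensionError(
                    f"buffer {name}: checkpoint shape {arr.shape} != {b.shape}"
                )
            b[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class ParameterList(Module):
    def __init__(self, params=()):
        super().__init__()
        self._list: list[Parameter] = []
        for p in params:
            self.append(p)

    def append(self, param: Parameter) -> None:
        self._parameters[str(len(self._list))] = param
        self._list.append(param)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    """Kaiming(fan-out)-initialized 2D convolution."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = False,
        *,
        rng: np.random.Generator,
    ):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ConfigError("channel counts must be divisible by groups")
        self.stride = stride
        self.padding = padding
        self.groups = groups
        k = kernel_size
        fan_out = out_channels * k * k // groups
        std = np.sqrt(2.0 / fan_out)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels // groups, k, k)).astype(
                np.float32
            )
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(
            x, self.weight, self.bias, self.stride, self.padding, self.groups
        )


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(
            x,
            self.weight,
            self.bias,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class Linear(Module):
    """Dense layer; ``init='zero'`` suits classifier heads (uniform initial loss)."""

    def __init__(
        self, in_features: int, out_features: int, bias: bool = True, *,
        rng, init: str = "uniform",
    ):
        super().__init__()
        if init == "zero":
            self.weight = Parameter(np.zeros((out_features, in_features), dtype=np.float32))
            self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None
            return
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features)).astype(np.float32)
        )
        self.bias = (
            Parameter(rng.uniform(-bound, bound, size=out_features).astype(np.float32))
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.maxpool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.avgpool2d(x, self.kernel_size, self.stride, self.padding)
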