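"""Neural-network modules built on the :mod:`camloc.nn.autograd` engine.

The module system mirrors the conventions of mainstream deep-learning
frameworks (parameter registration by attribute assignment, ``train``/``eval``
modes, state dicts of plain numpy arrays) so the model-building code reads
like any other CNN definition.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Parameter", "Module", "Sequential", "Identity", "Conv2d", "Linear",
    "BatchNorm2d", "ReLU", "SiLU", "Sigmoid", "MaxPool2d",
    "AdaptiveAvgPool2d", "UpsampleBilinear2d", "Dropout",
]


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
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

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- state ---------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: np.asarray(v).copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, p in params.items():
            p.data[...] = state[k]
        # buffers are re-bound by owner module
        for k in dict(self.named_buffers()):
            owner, _, leaf = k.rpartition(".")
            mod: Module = self
            if owner:
                for part in owner.split("."):
                    mod = mod._modules[part]
            mod._set_buffer(leaf, state[k].copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._order: list[str] = []
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
            self._order.append(str(i))

    def __iter__(self):
        return iter(getattr(self, n) for n in self._order)

    def __len__(self):
        return len(self._order)

    def __getitem__(self, i: int) -> Module:
        return getattr(self, self._order[i])

    def forward(self, x: Tensor) -> Tensor:
        for m in self:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def _rng(rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng()


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.stride, self.padding, self.groups = stride, padding, groups
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        # He-normal init, appropriate for the rectified nets built here
        std = np.sqrt(2.0 / fan_in)
        g = _rng(rng)
        self.weight = Parameter(g.normal(0.0, std,
                                         (out_channels, in_channels // groups, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                         self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        g = _rng(rng)
        self.weight = Parameter(g.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(g.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training and ag.is_grad_enabled():
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            m = self.momentum
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.data.reshape(c))
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * unbiased)
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class AdaptiveAvgPool2d(Module):
    """Global average pooling to 1x1 (the only size the models need)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3), keepdims=True)


class UpsampleBilinear2d(Module):
    def __init__(self, scale_factor: int = 2):
        super().__init__()
        self.scale_factor = scale_factor

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return ag.resize_bilinear(x, h * self.scale_factor, w * self.scale_factor)


class Dropout(Module):
    """Parameter-free placeholder (kept for architectural parity; the models
    here are trained at scales where dropout is counterproductive)."""

    def __init__(self, p: float = 0.0):
        super().__init__()
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        return x
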