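"""Layer/module containers with named-parameter trees and checkpoints."""

from __future__ import annotations

import numpy as np

from .functional import conv2d
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "Linear", "LayerNorm", "Sequential", "Identity", "ReLU", "SiLU"]


class Module:
    """Container of parameters and sub-modules, torch-style but tiny.

    Attributes that are :class:`Tensor` become parameters; attributes that
    are :class:`Module` (or lists of modules) become children.  Parameter
    names are slash-joined paths, which is also the checkpoint key format.
    """

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{path}/")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}/")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2-D convolution, He-normal initialised, bias on by default."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = cin * k * k
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def named_parameters(self, prefix: str = ""):
        yield f"{prefix}weight", self.weight
        if self.bias is not None:
            yield f"{prefix}bias", self.bias

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Layer normalisation over all non-batch axes of an NCHW grid.

    Statistics are computed per sample over (channel, height, width); the
    learnable affine scale/shift is per channel so the layer is agnostic to
    spatial size.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=axes, keepdims=True)
        return centred * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()
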