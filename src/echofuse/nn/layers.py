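"""Neural-network layers built on the autodiff engine.

Initialisation is explicit: every layer takes a ``numpy.random.Generator``
so that model construction is fully reproducible from a seed with no global
state.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from . import functional as F

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "Sequential",
    "SEBlock",
]


class Module:
    """Base class: tracks parameters and sub-modules by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mname}.")

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.astype(p.data.dtype, copy=True)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(arr: np.ndarray) -> Tensor:
    t = Tensor(np.asarray(arr, dtype=np.float32))
    t.requires_grad = True
    return t


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.weight = _param(w)
        self.bias = _param(np.zeros(n_out))

    def forward(self, x):
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, groups: int = 1,
                 dilation: int = 1):
        super().__init__()
        if pad is None:
            pad = (k - 1) // 2 * dilation
        fan_in = c_in // groups * k * k
        self.weight = _param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in // groups, k, k))
        )
        self.bias = _param(np.zeros(c_out))
        self.stride, self.pad, self.groups, self.dilation = stride, pad, groups, dilation

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad,
                        self.groups, self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 2, pad: int = 1):
        super().__init__()
        fan_in = c_in * k * k
        self.weight = _param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, k, k))
        )
        self.bias = _param(np.zeros(c_out))
        self.stride, self.pad = stride, pad

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride, self.pad)


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalisation with learnable affine.

    No running statistics: train and eval behave identically, which keeps
    single-threaded runs bit-reproducible.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = _param(np.ones((1, channels, 1, 1)))
        self.beta = _param(np.zeros((1, channels, 1, 1)))
        self.eps = eps

    def forward(self, x):
        m = x.mean(axis=(2, 3), keepdims=True)
        centred = x - m
        var = (centred * centred).mean(axis=(2, 3), keepdims=True)
        y = centred / (var + self.eps) ** 0.5
        return y * self.gamma + self.beta


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._order = list(mods)

    def forward(self, x):
        for m in self._order:
            x = m(x)
        return x


class SEBlock(Module):
    """Squeeze-and-excitation channel gating (used by the paper-scale preset)."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x):
        s = F.global_avg_pool(x)
        s = self.fc2(self.fc1(s).relu()).sigmoid()
        b, c = s.shape
        return x * s.reshape(b, c, 1, 1)
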