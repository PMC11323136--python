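"""Neural-network layers and the SGD optimizer on top of ``autodiff``.

Layout convention is NCHW throughout.  ``LayerNorm`` normalizes over the
channel axis at every spatial position (the encoder convention);
``BatchNorm2d`` keeps running statistics for inference (the decoder
convention).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable under no_grad


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(np.float32)


class Module:
    """Minimal module container with named parameters and train/eval modes."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpointing ------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing {sorted(missing)[:5]}, "
                f"unexpected {sorted(extra)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()
        self._load_buffers(state, "")

    def _load_buffers(self, state, prefix):
        for name in self._buffers:
            full = prefix + name
            self._buffers[name] = state[full].copy()
            object.__setattr__(self, name, self._buffers[name])
        for name, mod in self._modules.items():
            mod._load_buffers(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module) -> None:
        self._modules[str(len(self._list))] = mod
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.groups = stride, padding, groups
        self.in_channels, self.out_channels, self.kernel_size = \
            in_channels, out_channels, kernel_size
        self.weight = Parameter(trunc_normal(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Normalization over the channel axis at each spatial location (NCHW)."""

    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.channels = channels
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        c = self.channels
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum, self.channels = eps, momentum, channels
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))
        self.register_buffer("running_mean", np.zeros(channels, np.float32))
        self.register_buffer("running_var", np.ones(channels, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        c = self.channels
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            rm = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            rv = (1 - m) * self.running_var + m * var.data.reshape(c)
            self.register_buffer("running_mean", rm.astype(np.float32))
            self.register_buffer("running_var", rv.astype(np.float32))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            xc = x - mu
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


def make_activation(name: str) -> Module:
    if name == "relu":
        return ReLU()
    if name == "gelu":
        return GELU()
    raise ValueError(f"unknown activation {name!r}")


class SGD:
    """Stochastic gradient descent with momentum and decoupled-style weight
    decay added to the gradient (the classical convention)."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
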