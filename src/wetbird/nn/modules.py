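"""Layer/module abstractions on top of the autograd tensors."""
from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class: attribute registration, parameter traversal, train/eval."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor):
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_modules(self, prefix=""):
        yield prefix.rstrip("."), self
        for n, m in self._modules.items():
            yield from m.named_modules(prefix + n + ".")

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, sd: dict):
        own = dict(self.named_parameters())
        if set(own) != set(sd):
            missing = set(own) ^ set(sd)
            raise ValueError(f"state dict key mismatch: {sorted(missing)[:5]} ...")
        for n, p in own.items():
            if p.data.shape != sd[n].shape:
                raise ValueError(f"shape mismatch for {n}: {p.data.shape} vs {sd[n].shape}")
            p.data[...] = sd[n]

    def __call__(self, *a, **kw):
        return self.forward(*a, **kw)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(shape, fan_in, rng):
    bound = math.sqrt(1.0 / fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


_init_rng = np.random.default_rng(0)


def seed_init(seed: int):
    """Seed the weight-initialisation stream (used by the model builder)."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, stride=1, padding=0, dilation=1, groups=1, bias=True):
        super().__init__()
        if c1 % groups or c2 % groups:
            raise ValueError("channels must divide groups")
        kh, kw = (k, k) if isinstance(k, int) else tuple(k)
        self.c1, self.c2, self.k = c1, c2, (kh, kw)
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (c1 // groups) * kh * kw
        self.weight = Tensor(_kaiming((c2, c1 // groups, kh, kw), fan_in, _init_rng), requires_grad=True)
        self.bias = Tensor(_kaiming((c2,), fan_in, _init_rng), requires_grad=True) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            y = xc / (var + self.eps).sqrt()
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1) * unbias
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            y = (x - Tensor(mu)) * Tensor(1.0 / np.sqrt(var + self.eps))
        w = self.weight.reshape(1, self.c, 1, 1)
        b = self.bias.reshape(1, self.c, 1, 1)
        return y * w + b


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, k, stride=1, padding=0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding

    def forward(self, x):
        return F.maxpool2d(x, self.k, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest(x, self.scale)
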