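"""Neural-network modules built on the autograd engine."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

_GLOBAL_RNG = np.random.default_rng(0)


def manual_seed(seed: int):
    """Seed the RNG used for parameter initialisation."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -------------------------------------------------------------- traversal
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        buffers = getattr(self, "_buffers", ())
        for name in buffers:
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------- state dict
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: np.array(b, copy=True)
                      for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict, strict: bool = True):
        own = dict(self.named_parameters())
        missing = []
        for name, p in own.items():
            if name in state:
                p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.shape)
            elif strict:
                missing.append(name)
        for name, _ in self.named_buffers():
            if name in state:
                obj, attr = self._resolve(name)
                setattr(obj, attr, np.array(state[name], copy=True))
            elif strict:
                missing.append(name)
        if missing:
            raise KeyError(f"missing keys in state dict: {missing}")

    def _resolve(self, dotted: str):
        parts = dotted.split(".")
        obj = self
        for p in parts[:-1]:
            obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
        return obj, parts[-1]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self._modules = list(modules)

    def __getitem__(self, i):
        return self._modules[i]

    def __iter__(self):
        return iter(self._modules)

    def forward(self, x):
        for m in self._modules:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        bound = math.sqrt(2.0 / fan_in)  # Kaiming for (leaky) ReLU nets
        self.weight = Parameter(
            _GLOBAL_RNG.normal(0.0, bound, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        bound = math.sqrt(2.0 / in_f)
        self.weight = Parameter(_GLOBAL_RNG.normal(0.0, bound, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1)).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(np.float32)
            inv = (var + self.eps) ** -0.5
            xhat = centered * inv
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            xhat = (x - mu) * inv
        w = self.weight.reshape(1, -1, 1, 1)
        b = self.bias.reshape(1, -1, 1, 1)
        return xhat * w + b


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()
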