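"""Layer modules with torch-like parameter registration."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Parameter", "Sequential", "Conv2d", "BatchNorm2d",
           "Linear", "ReLU", "MaxPool2d", "GlobalAvgPool2d", "Identity",
           "kaiming_uniform"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He/Kaiming uniform, gain for ReLU (sqrt 2), fan-in mode."""
    bound = np.float32(np.sqrt(6.0 / fan_in))
    return (rng.random(size=shape, dtype=np.float32) * 2 - 1) * bound


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

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data
        for name, m in self._named_modules(""):
            for bname, buf in getattr(m, "_buffers", {}).items():
                out[f"{name}{bname}"] = buf
        return out

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.shape)
        for name, m in self._named_modules(""):
            for bname, buf in getattr(m, "_buffers", {}).items():
                buf[...] = np.asarray(state[f"{name}{bname}"]).reshape(buf.shape)

    def _named_modules(self, prefix):
        yield prefix, self
        for name, m in self._modules.items():
            yield from m._named_modules(prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(num_ch))
        self.bias = Parameter(np.zeros(num_ch))
        self._buffers = {
            "running_mean": np.zeros(num_ch, dtype=np.float32),
            "running_var": np.ones(num_ch, dtype=np.float32),
        }

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias,
                              self._buffers["running_mean"], self._buffers["running_var"],
                              self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(kaiming_uniform(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x):
        out = x @ self.weight.swapaxes(-1, -2)
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    """[B,C,H,W] -> [B,C]."""

    def forward(self, x):
        return x.mean(axis=(2, 3))


class Identity(Module):
    def forward(self, x):
        return x
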