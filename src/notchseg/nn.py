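"""Neural-network modules over the autodiff engine.

Layers follow the conv -> batch-norm -> ReLU idiom used throughout the
architecture.  Every module takes an explicit `numpy.random.Generator`
for weight initialisation so that network construction is fully seeded.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


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

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ------------------------------------------------

    def _buffers(self):
        """Override to expose non-trainable state (e.g. BN running stats)."""
        return {}

    def state_dict(self, prefix: str = "") -> dict:
        out = {prefix + k: p.data.copy() for k, p in self._params.items()}
        out.update({prefix + k: v.copy() for k, v in self._buffers().items()})
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=np.float64).copy()
        bufs = self._buffers()
        for k in bufs:
            bufs[k][...] = state[prefix + k]
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Conv2d(Module):
    """3x3-style 2D convolution with 'same' padding by default (odd kernels)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = True, padding: int | None = None):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding = stride, padding
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, ch: int, k: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.padding = k // 2
        std = np.sqrt(2.0 / (k * k))
        self.weight = Parameter(rng.normal(0.0, std, (ch, k, k)))
        self.bias = Parameter(np.zeros(ch)) if bias else None

    def forward(self, x):
        return T.depthwise_conv2d(x, self.weight, self.bias, self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, (in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            return g * xc * (var + self.eps) ** -0.5 + b
        mu = self.running_mean.reshape(1, -1, 1, 1)
        inv = (self.running_var.reshape(1, -1, 1, 1) + self.eps) ** -0.5
        return g * ((x - Tensor(mu)) * Tensor(inv)) + b


class LayerNorm(Module):
    """Normalises over the last axis (token feature dimension)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc * (var + self.eps) ** -0.5) + self.beta


def conv_bn_relu(in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 stride: int = 1) -> Sequential:
    return Sequential(
        Conv2d(in_ch, out_ch, k, rng, stride=stride, bias=False),
        BatchNorm2d(out_ch),
        ReLU(),
    )


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= self.lr * (
                (m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.weight_decay * p.data
            )
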