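"""Layer abstractions over the autograd engine (Conv2d, BatchNorm2d, ...)."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reset the generator used for weight initialisation (call before building)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    """A trainable tensor; always float32."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.requires_grad = True  # survive construction under no_grad


class Module:
    """Minimal container with parameter traversal and train/eval switching."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal -----------------------------------------------------------
    def named_members(self, prefix=""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val, None
            elif isinstance(val, Module):
                yield from val.named_members(f"{full}.")
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield from m.named_members(f"{full}.{i}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield full, None, val  # buffer

    def named_parameters(self, prefix=""):
        for name, p, _ in self.named_members(prefix):
            if p is not None:
                yield name, p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, ModuleList):
                for m in val:
                    yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- modes / gradients -----------------------------------------------------
    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation -----------------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for name, p, buf in self.named_members():
            out[name] = (p.data if p is not None else buf).copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for name, p, buf in self.named_members():
            src = state[name]
            if p is not None:
                if p.data.shape != src.shape:
                    raise ValueError(f"{name}: shape {src.shape} != {p.data.shape}")
                p.data = np.asarray(src, dtype=np.float32).copy()
            else:
                buf[...] = src


class ModuleList(list):
    """A plain list that Module traversal understands."""


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = ModuleList(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, dilation=1, bias=True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.weight = Parameter(_INIT_RNG.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x):
        return ag.batch_norm2d(x, self.weight, self.bias,
                               self.running_mean, self.running_var,
                               training=self.training, momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return ag.max_pool2d(x, self.kernel, self.stride, self.padding)


class UpsampleBilinear(Module):
    """Scale spatial size by an integer factor with bilinear interpolation."""

    def __init__(self, factor=2):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        h, w = x.data.shape[2], x.data.shape[3]
        return ag.resize_bilinear(x, h * self.factor, w * self.factor)


def conv_bn_relu(in_ch, out_ch, kernel, stride=1, padding=0, dilation=1):
    return Sequential(
        Conv2d(in_ch, out_ch, kernel, stride=stride, padding=padding,
               dilation=dilation, bias=False),
        BatchNorm2d(out_ch),
        ReLU(),
    )
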