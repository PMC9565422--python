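"""Neural-network modules built on the autograd tape.

Weight initialization follows the GAN-literature convention of
normal(0, 0.02) for convolutional kernels; linear layers use uniform
fan-in scaling.  Every module draws its initial weights from an explicit
`numpy.random.Generator` so that model construction is reproducible.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: parameter registry, train/eval mode, state dict."""

    def __init__(self):
        self._params: OrderedDict[str, Parameter] = OrderedDict()
        self._modules: OrderedDict[str, Module] = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self, prefix: str = "") -> OrderedDict:
        out = OrderedDict()
        for k, p in self._params.items():
            out[prefix + k] = p.data.copy()
        for k, v in self.__dict__.items():
            if k.startswith("running_"):
                out[prefix + k] = np.array(v, copy=True)
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = "") -> None:
        for k, p in self._params.items():
            p.data = np.array(state[prefix + k], copy=True)
        for k in list(self.__dict__):
            if k.startswith("running_") and prefix + k in state:
                object.__setattr__(self, k, np.array(state[prefix + k], copy=True))
        for k, m in self._modules.items():
            m.load_state_dict(state, prefix + k + ".")

    def copy_from(self, other: "Module") -> None:
        self.load_state_dict(other.state_dict())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True,
                 rng=None, dtype=np.float32, init_std=0.02):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(rng.normal(0.0, init_std,
                                           (out_ch, in_ch, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Transposed convolution via zero-dilation followed by a stride-1 conv.

    Output size is (H-1)*stride - 2*padding + kernel.
    """

    def __init__(self, in_ch, out_ch, kernel, stride=2, padding=1, bias=True,
                 rng=None, dtype=np.float32, init_std=0.02):
        super().__init__()
        rng = rng or np.random.default_rng()
        if kernel - 1 - padding < 0:
            raise ValueError("padding must be <= kernel-1")
        self.stride, self.padding, self.kernel = stride, padding, kernel
        self.weight = Parameter(rng.normal(0.0, init_std,
                                           (out_ch, in_ch, kernel, kernel)).astype(dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x):
        xd = ag.zero_dilate(x, self.stride)
        return ag.conv2d(xd, self.weight, self.bias, 1, self.kernel - 1 - self.padding)


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_f)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_f, out_f)).astype(dtype))
        self.bias = Parameter(np.zeros(out_f, dtype=dtype)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class InstanceNorm2d(Module):
    def __init__(self, ch, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))

    def forward(self, x):
        return ag.instance_norm(x, self.gamma, self.beta)


class BatchNorm1d(Module):
    def __init__(self, ch, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(ch, dtype=dtype))
        self.beta = Parameter(np.zeros(ch, dtype=dtype))
        self.momentum = momentum
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)

    def forward(self, x):
        if self.training:
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        return ag.batch_norm(x, self.gamma, self.beta,
                             self.running_mean, self.running_var, self.training)


class Dropout(Module):
    """Inverted dropout; active only in training mode.

    The mask stream comes from the generator passed at construction so the
    whole training run is reproducible from one seed.
    """

    def __init__(self, p=0.5, rng=None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        if not self.training or self.p == 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope=0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return ag.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x):
        return ag.tanh(x)


class AvgPool2d(Module):
    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return ag.avg_pool2d(x, self.k)


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], -1)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
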