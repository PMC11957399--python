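"""Network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .tensor import (Tensor, axis_linmap, batchnorm, conv3d, conv_transpose3d,
                     maxpool3d, relu, upsample_matrix)

__all__ = ["Module", "Parameter", "Conv3d", "ConvTranspose3d", "BatchNorm3d",
           "MaxPool3d", "Upsample", "Sequential", "ReLU"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        for mod in self.modules():
            for v in mod.__dict__.values():
                if isinstance(v, Parameter):
                    yield v

    def train(self):
        for mod in self.modules():
            mod.training = True
        return self

    def eval(self):
        for mod in self.modules():
            mod.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, x):
        return self.forward(x)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- flat (de)serialization ---------------------------------------------
    def state_arrays(self):
        """Ordered list of all parameter and buffer arrays (views)."""
        out = []
        for mod in self.modules():
            for name in sorted(mod.__dict__):
                v = mod.__dict__[name]
                if isinstance(v, Parameter):
                    out.append(v.data)
                elif isinstance(v, np.ndarray) and name.startswith("running_"):
                    out.append(v)
        return out

    def load_state_arrays(self, arrays):
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state length mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError("state shape mismatch")
            dst[...] = src


class Conv3d(Module):
    """Stride-1 'same' 3-D convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel ** 3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std,
                                           (out_ch, in_ch, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """Kernel-2 stride-2 up-convolution (doubles every spatial axis)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / (in_ch * 8))
        self.weight = Parameter(rng.normal(0.0, std, (in_ch, out_ch, 2, 2, 2)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv_transpose3d(x, self.weight, self.bias)


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        c = self.gamma.shape[0]
        shape = (1, c, 1, 1, 1)
        if self.training:
            out, mu, var = batchnorm(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean += m * (mu - self.running_mean)
            self.running_var += m * (var - self.running_var)
            return out
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shiftv = self.beta.data - scale * self.running_mean
        return x * Tensor(scale.reshape(shape)) + Tensor(shiftv.reshape(shape))


class MaxPool3d(Module):
    def __init__(self, factors=(2, 2, 2)):
        super().__init__()
        self.factors = tuple(factors)

    def forward(self, x):
        return maxpool3d(x, self.factors)


class Upsample(Module):
    """Trilinear upsampling by integer factors (align_corners=False)."""

    def __init__(self, factors=(2, 2, 2)):
        super().__init__()
        self.factors = tuple(factors)
        self._cache: dict = {}

    def forward(self, x):
        for ax, f in zip((2, 3, 4), self.factors):
            if f == 1:
                continue
            n = x.shape[ax]
            key = (n, f)
            if key not in self._cache:
                self._cache[key] = upsample_matrix(n, f)
            x = axis_linmap(x, self._cache[key], axis=ax)
        return x


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
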