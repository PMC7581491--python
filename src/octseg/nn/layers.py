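"""Layer modules over the autograd engine (NCHW float32)."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter collection and state (de)serialization."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self):
        """All learnable parameters plus running statistics, in a stable order."""
        arrays = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                arrays.append(v.data)
            elif isinstance(v, np.ndarray):
                arrays.append(v)
            elif isinstance(v, Module):
                arrays.extend(v.state_arrays())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        arrays.extend(item.state_arrays())
        return arrays

    def get_state(self):
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state):
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            if dst.shape != src.shape:
                raise ValueError("state shape mismatch")
            dst[...] = src


def _he_normal(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Same-padded stride-1 convolution, He-initialized."""

    def __init__(self, cin, cout, k, rng):
        self.w = Tensor(_he_normal(rng, (cout, cin, k, k), cin * k * k),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ag.conv2d(x, self.w, self.b)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin, cout, rng):
        self.w = Tensor(_he_normal(rng, (cin, cout, 2, 2), cin * 4),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ag.conv_transpose2x2(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training):
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training,
                              momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, n_in, n_out, rng):
        self.w = Tensor(_he_normal(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ag.add(ag.matmul(x, self.w), self.b)
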