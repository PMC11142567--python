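"""Neural-network building blocks on top of the autodiff core.

Layout convention is NHWC throughout: activations are (batch, height,
width, channels). Weights are He-normal initialized (std = sqrt(2/fan_in))
from a caller-supplied :class:`numpy.random.Generator`, biases start at
zero, so construction is fully reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, conv2d, conv_transpose2d, relu


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype=np.float32) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Module:
    """Base class providing recursive parameter/buffer discovery."""

    training: bool = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for key, value in self.__dict__.items():
            path = f"{prefix}{key}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        """Non-learnable state (batch-norm running statistics)."""
        for key, value in self.__dict__.items():
            path = f"{prefix}{key}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{path}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}.")
            elif key.startswith("running_"):
                yield path, value

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for module in self.modules():
            module.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    """Affine map on the last axis."""

    def __init__(self, fan_in: int, fan_out: int, bias: bool = True, *, rng: np.random.Generator, dtype=np.float32):
        self.weight = Parameter(he_normal(rng, (fan_in, fan_out), fan_in, dtype))
        self.bias = Parameter(np.zeros(fan_out, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        *,
        stride: int = 1,
        dilation: int = 1,
        padding: str = "same",
        bias: bool = True,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        fan_in = kernel * kernel * c_in
        self.weight = Parameter(he_normal(rng, (kernel, kernel, c_in, c_out), fan_in, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype)) if bias else None
        self.stride = stride
        self.dilation = dilation
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, dilation=self.dilation, padding=self.padding)


class ConvTranspose2d(Module):
    """2x2/stride-2 transposed convolution (exact spatial doubling)."""

    def __init__(self, c_in: int, c_out: int, *, rng: np.random.Generator, dtype=np.float32):
        fan_in = c_in  # each output pixel sees exactly one input position
        self.weight = Parameter(he_normal(rng, (2, 2, c_in, c_out), fan_in, dtype))
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias)


class BatchNorm(Module):
    """Batch normalization over (batch, height, width) per channel.

    Training mode normalizes by batch statistics and updates running
    statistics with momentum; eval mode uses the running statistics, so
    inference is deterministic.
    """

    def __init__(self, channels: int, *, eps: float = 1e-5, momentum: float = 0.9, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 1, 2), keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1.0 - self.momentum) * mu.data.reshape(-1)
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1.0 - self.momentum) * var.data.reshape(-1)
            ).astype(self.running_var.dtype)
            xhat = centered * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class ConvBnRelu(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, *, stride: int = 1, rng: np.random.Generator, dtype=np.float32):
        self.conv = Conv2d(c_in, c_out, kernel, stride=stride, rng=rng, dtype=dtype)
        self.bn = BatchNorm(c_out, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))
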