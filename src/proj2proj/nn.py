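"""Network building blocks and the Adam optimizer, on the autodiff engine.

Single-sample layout throughout (channels, height, width): the training
protocol uses batch size one, so no batch axis is carried.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module", "Conv2d", "InstanceNorm2d", "ReLU", "LeakyReLU", "Sigmoid",
    "UpsampleNearest2", "Sequential", "ResidualBlock", "Adam",
    "save_params", "load_params",
]


class Module:
    """Base class: parameter collection and call protocol."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
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

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 trainable: bool = True):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization
        self.weight = Tensor(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)),
                             requires_grad=trainable)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=trainable)

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class InstanceNorm2d(Module):
    def __init__(self, channels: int, trainable: bool = True):
        self.gamma = Tensor(np.ones((channels, 1, 1)), requires_grad=trainable)
        self.beta = Tensor(np.zeros((channels, 1, 1)), requires_grad=trainable)

    def forward(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return ad.leaky_relu(x, self.alpha)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.sigmoid(x)


class UpsampleNearest2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.upsample_nearest2(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ResidualBlock(Module):
    """conv3-IN-ReLU-conv3-IN with an identity skip.

    ``zero_init_last`` sets the final normalization gain to zero so a freshly
    built block is the identity map — a common stabilizer for deep stacks,
    and it makes the identity property directly testable.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 zero_init_last: bool = False):
        self.body = Sequential(
            Conv2d(channels, channels, 3, rng=rng),
            InstanceNorm2d(channels),
            ReLU(),
            Conv2d(channels, channels, 3, rng=rng),
            InstanceNorm2d(channels),
        )
        if zero_init_last:
            self.body.layers[-1].gamma.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(x, self.body(x))


class Adam:
    """Adam with the (0.5, 0.999) moments customary for adversarial training."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def save_params(module: Module, path) -> None:
    arrays = {f"p{i}": p.data for i, p in enumerate(module.parameters())}
    np.savez(path, **arrays)


def load_params(module: Module, path) -> None:
    with np.load(path) as data:
        params = module.parameters()
        if len(data.files) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            p.data[...] = data[f"p{i}"]
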