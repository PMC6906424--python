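"""Generator and discriminator architectures for projection translation.

The generator is an encoder-decoder with residual blocks.  The customary
design puts the whole residual stack at the lowest-resolution level, where the
global layout of the image is decided; the variant proposed here relocates the
residual capacity to the highest-resolution levels, where sharp borders and
edges are synthesized — at the price of narrower feature widths there, so that
both variants can be built from one parameter budget and compared fairly.

The discriminator is a patch critic: a strided convolutional stack mapping a
(conditioning MR projection, candidate X-ray projection) channel pair to a 2D
map of real/fake scores, one per receptive-field patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import (
    Adam,  # noqa: F401  (re-exported convenience)
    Conv2d,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    ReLU,
    ResidualBlock,
    Sequential,
    Sigmoid,
    UpsampleNearest2,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "Generator",
    "PatchDiscriminator",
    "build_generator",
    "build_discriminator",
    "match_generator_specs",
]


def _conv_params(cin: int, cout: int, k: int) -> int:
    return cout * cin * k * k + cout


def _in_params(c: int) -> int:
    return 2 * c


def _res_params(c: int) -> int:
    return 2 * (_conv_params(c, c, 3) + _in_params(c))


@dataclass
class GeneratorSpec:
    """Architecture hyper-parameters of the translation generator.

    ``residual_counts[l]`` is the number of residual blocks operating at
    resolution level ``l`` (0 = finest, ``n_levels`` = coarsest; the blocks
    for l < n_levels sit on the decoder path).  ``high_res`` placement halves
    the channel widths of the two finest levels relative to the plain doubling
    plan, trading width for the relocated residual capacity.
    """

    n_levels: int = 2
    base_channels: int = 12
    residual_placement: str = "high_res"  # or "bottleneck"
    residual_counts: list[int] | None = None
    memory_budget: int | None = None
    upsample: str = "nearest_conv"  # or "transposed" (not built; flag reserved)

    def __post_init__(self) -> None:
        if self.residual_placement not in ("high_res", "bottleneck"):
            raise ValueError(f"unknown residual_placement {self.residual_placement!r}")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.residual_counts is None:
            if self.residual_placement == "bottleneck":
                self.residual_counts = [0] * self.n_levels + [6]
            else:
                counts = [0] * (self.n_levels + 1)
                counts[0] = 3
                counts[min(1, self.n_levels)] = 3
                self.residual_counts = counts
        if len(self.residual_counts) != self.n_levels + 1:
            raise ValueError("residual_counts must have n_levels + 1 entries")
        if self.residual_placement == "bottleneck":
            if any(c != 0 for c in self.residual_counts[:-1]) or self.residual_counts[-1] < 1:
                raise ValueError("bottleneck placement puts all residual blocks at the coarsest level")
        else:
            if self.residual_counts[0] < 1 or self.residual_counts[min(1, self.n_levels)] < 1:
                raise ValueError("high_res placement needs residual blocks at each of the two finest levels")

    def channel_plan(self) -> list[int]:
        widths = [self.base_channels * 2**l for l in range(self.n_levels + 1)]
        if self.residual_placement == "high_res":
            for l in (0, 1):
                if l <= self.n_levels:
                    widths[l] = max(2, widths[l] // 2)
        return widths

    def parameter_count(self) -> int:
        w = self.channel_plan()
        total = _conv_params(1, w[0], 7) + _in_params(w[0])  # stem
        for l in range(1, self.n_levels + 1):  # encoder
            total += _conv_params(w[l - 1], w[l], 4) + _in_params(w[l])
        total += self.residual_counts[-1] * _res_params(w[-1])  # bottleneck blocks
        for l in range(self.n_levels, 0, -1):  # decoder
            total += _conv_params(w[l], w[l - 1], 3) + _in_params(w[l - 1])
            total += self.residual_counts[l - 1] * _res_params(w[l - 1])
        total += _conv_params(w[0], 1, 7)  # output head (linear)
        return total


@dataclass
class DiscriminatorSpec:
    """Patch discriminator hyper-parameters."""

    n_layers: int = 3
    base_channels: int = 16
    in_channels: int = 2  # conditioning MR + candidate X-ray

    @property
    def receptive_field(self) -> int:
        strides = [2] * (self.n_layers - 1) + [1, 1]
        rf = 1
        for s in reversed(strides):
            rf = rf * s + (4 - s)
        return rf


class Generator(Module):
    """Encoder-decoder translation network; maps (1, H, W) -> (1, H, W)."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        w = spec.channel_plan()
        L = spec.n_levels
        stages: list[tuple[int, Module]] = []
        stages.append((0, Sequential(Conv2d(1, w[0], 7, rng=rng), InstanceNorm2d(w[0]), ReLU())))
        for l in range(1, L + 1):
            stages.append((l, Sequential(Conv2d(w[l - 1], w[l], 4, stride=2, pad=1, rng=rng),
                                         InstanceNorm2d(w[l]), ReLU())))
        for _ in range(spec.residual_counts[-1]):
            stages.append((L, ResidualBlock(w[-1], rng=rng, zero_init_last=True)))
        for l in range(L, 0, -1):
            stages.append((l - 1, Sequential(UpsampleNearest2(),
                                             Conv2d(w[l], w[l - 1], 3, rng=rng),
                                             InstanceNorm2d(w[l - 1]), ReLU())))
            for _ in range(spec.residual_counts[l - 1]):
                stages.append((l - 1, ResidualBlock(w[l - 1], rng=rng, zero_init_last=True)))
        stages.append((0, Conv2d(w[0], 1, 7, rng=rng)))
        self.stages = stages

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for _, m in self.stages:
            params.extend(m.parameters())
        return params

    def forward(self, x: Tensor) -> Tensor:
        _, H, W = x.data.shape
        div = 2**self.spec.n_levels
        if H % div or W % div:
            raise ValueError(f"input size {H}x{W} not divisible by 2^{self.spec.n_levels}")
        for _, m in self.stages:
            x = m(x)
        return x

    def parameter_allocation(self) -> dict[int, int]:
        """Parameter count per resolution level (0 = finest)."""
        alloc: dict[int, int] = {}
        for level, m in self.stages:
            alloc[level] = alloc.get(level, 0) + m.n_parameters()
        return alloc

    def translate(self, image: np.ndarray) -> np.ndarray:
        """Run inference on a 2D numpy image."""
        out = self.forward(Tensor(image[None, :, :]))
        return out.data[0]


class PatchDiscriminator(Module):
    """Strided conv stack -> sigmoid patch-score map in (0, 1)."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        layers: list[Module] = [Conv2d(spec.in_channels, spec.base_channels, 4, stride=2, pad=1, rng=rng),
                                LeakyReLU(0.2)]
        ch = spec.base_channels
        for i in range(1, spec.n_layers):
            nxt = spec.base_channels * 2**i
            stride = 2 if i < spec.n_layers - 1 else 1
            layers += [Conv2d(ch, nxt, 4, stride=stride, pad=1, rng=rng),
                       InstanceNorm2d(nxt), LeakyReLU(0.2)]
            ch = nxt
        layers += [Conv2d(ch, 1, 4, stride=1, pad=1, rng=rng), Sigmoid()]
        self.net = Sequential(*layers)

    def forward(self, pair: Tensor) -> Tensor:
        if pair.data.shape[0] != self.spec.in_channels:
            raise ValueError(
                f"discriminator expects {self.spec.in_channels} stacked channels, got {pair.data.shape[0]}")
        return self.net(pair)


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed=seed)


def match_generator_specs(
    budget_params: int = 100_000,
    n_levels: int = 2,
    max_base: int = 256,
) -> tuple[GeneratorSpec, GeneratorSpec]:
    """Build (high_res, bottleneck) specs from one parameter budget.

    Mirrors the comparability contract of matched-capacity ablations: for each
    variant the base width is chosen so its parameter count is as close as
    possible to the budget, which keeps the two counts within a few percent of
    each other.
    """
    specs = []
    for placement in ("high_res", "bottleneck"):
        best = None
        for base in range(2, max_base + 1):
            spec = GeneratorSpec(n_levels=n_levels, base_channels=base,
                                 residual_placement=placement, memory_budget=budget_params)
            err = abs(spec.parameter_count() - budget_params)
            if best is None or err < best[0]:
                best = (err, spec)
        specs.append(best[1])
    return specs[0], specs[1]
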