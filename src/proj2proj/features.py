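"""Pluggable fixed feature extractors for the feature-matching loss.

The feature-matching loss compares activations of a *fixed* network (its
parameters are never updated) on the generated and label images.  Any callable
mapping a single-channel image tensor to an ordered list of activation stacks
can be plugged in — e.g. a wrapper around a pretrained perceptual network
tapped after each pre-pooling stage.  The default here is a seeded random
convolutional extractor: random convolutional features approximately preserve
image distances, need no downloaded weights, and make every test
deterministic.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, Module

__all__ = ["FeatureExtractor", "RandomConvFeatureExtractor", "IdentityFeatureExtractor"]


class FeatureExtractor(Protocol):
    """Callable: (1, H, W) image tensor -> ordered list of activation stacks."""

    def __call__(self, image: Tensor) -> list[Tensor]: ...


class IdentityFeatureExtractor:
    """Single tap returning the image itself; useful for closed-form checks."""

    def __call__(self, image: Tensor) -> list[Tensor]:
        return [image]


class RandomConvFeatureExtractor(Module):
    """Fixed-seed random convolutional feature pyramid.

    Each stage is conv3x3 -> leaky ReLU, tapped before a 2x2 average pooling
    that feeds the next stage.  Leaky activations keep gradients alive
    everywhere.  Parameters are frozen (``requires_grad=False``): identical
    inputs always yield identical activations.
    """

    def __init__(self, seed: int = 0, n_stages: int = 3, base_channels: int = 8):
        rng = np.random.default_rng(seed)
        self.convs: list[Conv2d] = []
        ch_in = 1
        for s in range(n_stages):
            ch_out = base_channels * 2**s
            self.convs.append(Conv2d(ch_in, ch_out, 3, rng=rng, trainable=False))
            ch_in = ch_out

    def __call__(self, image: Tensor) -> list[Tensor]:
        taps: list[Tensor] = []
        x = image
        for i, conv in enumerate(self.convs):
            x = ad.leaky_relu(conv(x), 0.2)
            taps.append(x)
            if i < len(self.convs) - 1:
                x = ad.avg_pool2(x)
        return taps
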