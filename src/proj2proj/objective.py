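"""The training objective: conditional adversarial loss, feature-matching
loss, and their edge-weighted combination.

The discriminator is conditional: it scores (MR input, candidate) pairs.  Its
objective is the standard cross-entropy — maximize log D(I, L) + log(1 - D(I, G))
— and the generator minimizes the non-saturating -log D(I, G).  The
feature-matching term is the mean absolute difference of fixed-network
activations per tapped layer, summed over layers.  Both terms are produced as
*unreduced* maps (per-patch scores; per-layer activation differences) so the
edge weight map can be resampled to each map's resolution, broadcast across
channels, and applied before the mean reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .edges import EdgeWeightMap, bilinear_resize
from .projector import ProjectionImage

__all__ = ["LossBreakdown", "gan_loss", "feature_matching_loss", "combined_objective"]

_EPS = 1e-8  # keeps log terms finite when the discriminator saturates


@dataclass
class LossBreakdown:
    """Scalar summary plus the graph tensors needed for the two update steps."""

    gan_term: float
    fm_term: float
    weighted_total: float
    fm_per_layer: list[float]
    generator_loss: Tensor
    discriminator_loss: Tensor


def _as_image_tensor(img, requires_grad: bool = False) -> Tensor:
    if isinstance(img, Tensor):
        return img
    pixels = img.pixels if isinstance(img, ProjectionImage) else np.asarray(img)
    t = Tensor(pixels[None, :, :] if pixels.ndim == 2 else pixels)
    t.requires_grad = requires_grad
    return t


def gan_loss(label, generated, input_mr, discriminator) -> tuple[Tensor, Tensor]:
    """Unreduced conditional GAN terms.

    Returns ``(generator_term_map, discriminator_term_map)``: the generator
    map is -log D(I, G) per patch; the discriminator map is
    -(log D(I, L) + log(1 - D(I, G_detached))) per patch.
    """
    L = _as_image_tensor(label)
    G = _as_image_tensor(generated)
    I = _as_image_tensor(input_mr)
    if not (L.shape == G.shape == I.shape):
        raise ValueError("label, generated and input images must share shape")

    d_real = discriminator(ad.concat([I, L], axis=0))
    d_fake_detached = discriminator(ad.concat([I.detach(), G.detach()], axis=0))
    d_fake = discriminator(ad.concat([I, G], axis=0))

    generator_map = ad.neg(ad.log(d_fake, _EPS))
    one_minus = ad.sub(Tensor(np.ones_like(d_fake_detached.data)), d_fake_detached)
    discriminator_map = ad.neg(ad.add(ad.log(d_real, _EPS), ad.log(one_minus, _EPS)))
    return generator_map, discriminator_map


def feature_matching_loss(label, generated, extractor) -> tuple[Tensor, list[Tensor]]:
    """Feature-matching loss: per tapped layer the mean absolute activation
    difference (normalized by the layer's element count), summed over layers.

    Returns the scalar and the unreduced per-layer |difference| maps.
    """
    L = _as_image_tensor(label)
    G = _as_image_tensor(generated)
    acts_L = extractor(L)
    acts_G = extractor(G)
    diff_maps = [ad.abs_(ad.sub(aL, aG)) for aL, aG in zip(acts_L, acts_G)]
    total: Tensor | None = None
    for dm in diff_maps:
        term = ad.mean(dm)
        total = term if total is None else ad.add(total, term)
    return total, diff_maps


def _weighted_mean(term_map: Tensor, weights: np.ndarray) -> Tensor:
    """Resample the weight map to the term map's spatial shape (bilinear),
    broadcast across channels, multiply, and mean-reduce."""
    h, w = term_map.data.shape[-2], term_map.data.shape[-1]
    wmap = bilinear_resize(weights, (h, w))
    return ad.mean(ad.mul(term_map, Tensor(wmap)))


def combined_objective(
    label,
    generated,
    input_mr,
    discriminator,
    extractor,
    weight_map: EdgeWeightMap | np.ndarray,
    gan_weight: float = 1.0,
    fm_weight: float = 1.0,
) -> LossBreakdown:
    """Edge-weighted combination of the adversarial and feature-matching terms.

    Every unreduced term map is multiplied elementwise by the weight map
    resampled (bilinear) to that map's resolution, then mean-reduced;
    ``weighted_total`` is the weighted GAN term plus the weighted FM term.
    The same weighting is applied to the discriminator's own objective so both
    players see the edge-emphasized game.
    """
    weights = weight_map.weights if isinstance(weight_map, EdgeWeightMap) else np.asarray(weight_map)
    L = _as_image_tensor(label)
    if weights.shape != L.data.shape[-2:]:
        raise ValueError(
            f"weight map shape {weights.shape} must match label resolution {L.data.shape[-2:]}")

    g_map, d_map = gan_loss(label, generated, input_mr, discriminator)
    fm_scalar, fm_maps = feature_matching_loss(label, generated, extractor)

    weighted_gan = _weighted_mean(g_map, weights)
    weighted_fm: Tensor | None = None
    for dm in fm_maps:
        term = _weighted_mean(dm, weights)
        weighted_fm = term if weighted_fm is None else ad.add(weighted_fm, term)

    generator_loss = ad.add(
        ad.mul(Tensor(gan_weight), weighted_gan), ad.mul(Tensor(fm_weight), weighted_fm)
    )
    discriminator_loss = _weighted_mean(d_map, weights)

    return LossBreakdown(
        gan_term=float(ad.mean(g_map).item()),
        fm_term=float(fm_scalar.item()),
        weighted_total=float(generator_loss.item()),
        fm_per_layer=[float(ad.mean(dm).item()) for dm in fm_maps],
        generator_loss=generator_loss,
        discriminator_loss=discriminator_loss,
    )
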