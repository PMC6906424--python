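"""Masked image-quality metrics for projection translation.

Projection images contain large homogeneous air regions that are trivially
reproduced and would optimistically bias error metrics; MAE and PSNR are
therefore restricted to pixels that are nonzero in the label image.  SSIM is
computed over the full image with the standard 11x11 Gaussian window.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .projector import ProjectionImage

__all__ = ["masked_mae_percent", "masked_psnr", "ssim"]


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ProjectionImage) else np.asarray(img, dtype=np.float64)


def _prepare(generated, label, mask):
    g = _pixels(generated)
    l = _pixels(label)
    if g.shape != l.shape:
        raise ValueError("generated and label images must share shape")
    if mask is None:
        mask = l != 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != l.shape:
            raise ValueError("mask must share the image shape")
    if not mask.any():
        raise ValueError("label mask is empty (all-zero label)")
    return g, l, mask


def masked_mae_percent(generated, label, mask: np.ndarray | None = None) -> float:
    """Mean absolute error in percent over the nonzero-label mask.

    Both images are min-max scaled by the *label's* range, so 100% corresponds
    to the label's full dynamic range.  ``mask`` overrides the default
    nonzero-label mask (e.g. a mask from the raw label when the images passed
    in are normalized).
    """
    g, l, mask = _prepare(generated, label, mask)
    lo, hi = float(l.min()), float(l.max())
    if hi == lo:
        raise ValueError("label has zero dynamic range")
    scale = hi - lo
    gs = (g - lo) / scale
    ls = (l - lo) / scale
    return float(np.mean(np.abs(gs[mask] - ls[mask])) * 100.0)


def masked_psnr(generated, label, mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio, 10 log10(range^2 / MSE), with the MSE taken
    over the nonzero-label mask and the peak from the label's range.
    Identical images return +inf."""
    g, l, mask = _prepare(generated, label, mask)
    rng = float(l.max() - l.min())
    if rng == 0:
        raise ValueError("label has zero dynamic range")
    mse = float(np.mean((g[mask] - l[mask]) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(rng**2 / mse))


def ssim(generated, label) -> float:
    """Structural similarity over the full image: 11x11 Gaussian window
    (sigma 1.5), K1 = 0.01, K2 = 0.03, data range from the label."""
    g = _pixels(generated)
    l = _pixels(label)
    if g.shape != l.shape:
        raise ValueError("generated and label images must share shape")
    rng = float(l.max() - l.min())
    if rng == 0:
        raise ValueError("label has zero dynamic range")
    return float(
        structural_similarity(
            l,
            g,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=rng,
        )
    )
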