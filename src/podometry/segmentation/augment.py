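"""Paired geometric augmentation of an image and its label mask.

The same transform is applied to both arrays; masks are warped with
nearest-neighbor interpolation so the label set is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "augment", "flip_horizontal", "flip_vertical",
           "rotate90", "elastic_deform"]


@dataclass(frozen=True)
class AugmentConfig:
    enabled: bool = True
    flips: bool = True
    rotations: bool = True      # multiples of 90 degrees
    elastic: bool = True
    elastic_alpha: float = 8.0  # displacement amplitude, px
    elastic_sigma: float = 12.0  # displacement smoothness, px


def flip_horizontal(image, mask):
    return image[:, ::-1].copy(), mask[:, ::-1].copy()


def flip_vertical(image, mask):
    return image[::-1, :].copy(), mask[::-1, :].copy()


def rotate90(image, mask, k: int = 1):
    return np.rot90(image, k).copy(), np.rot90(mask, k).copy()


def elastic_deform(image, mask, alpha: float, sigma: float,
                   rng: np.random.Generator):
    """Smooth random displacement field applied to both arrays."""
    h, w = image.shape
    dy = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma) * alpha
    dx = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma) * alpha
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    coords = [rr + dy, cc + dx]
    img = ndimage.map_coordinates(image, coords, order=1, mode="reflect")
    msk = ndimage.map_coordinates(mask, coords, order=0, mode="reflect")
    return img, msk


def augment(image, mask, config: AugmentConfig, seed: int):
    """Random seeded augmentation; identity when disabled.

    Same seed, same inputs -> identical outputs.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask must be aligned")
    if not config.enabled:
        return image, mask
    rng = np.random.default_rng(seed)
    if config.flips and rng.random() < 0.5:
        image, mask = flip_horizontal(image, mask)
    if config.flips and rng.random() < 0.5:
        image, mask = flip_vertical(image, mask)
    if config.rotations:
        k = int(rng.integers(0, 4))
        if k:
            image, mask = rotate90(image, mask, k)
    if config.elastic and rng.random() < 0.5:
        image, mask = elastic_deform(image, mask, config.elastic_alpha,
                                     config.elastic_sigma, rng)
    return image, mask
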