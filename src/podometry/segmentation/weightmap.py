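"""Border-emphasizing per-pixel loss weights.

The loss weight of each pixel is a class-balance term plus a border term
``w0 · exp(−(d1 + d2)² / (2σ²))``, where d1 and d2 are the distances to
the nearest and second-nearest labeled object.  The border term is large
only in the narrow ridge separating two nearby objects, forcing the
network to learn the separating background between touching nuclei; with
fewer than two objects it is zero everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["WeightMapParams", "make_weight_map"]


@dataclass(frozen=True)
class WeightMapParams:
    w0: float = 10.0
    sigma: float = 5.0  # px
    class_balance: bool = True

    def __post_init__(self) -> None:
        if self.w0 <= 0 or self.sigma <= 0:
            raise ValueError("w0 and sigma must be positive")


def make_weight_map(label_mask: np.ndarray,
                    params: WeightMapParams = WeightMapParams()) -> np.ndarray:
    """Weight grid for a labeled mask (0 = background).

    The class-balance term gives foreground and background pixels weights
    inversely proportional to their frequency (normalized to mean 1);
    with ``class_balance=False`` it is 1 everywhere.
    """
    labels = np.asarray(label_mask)
    if labels.ndim != 2:
        raise ValueError("label mask must be 2D")
    fg = labels > 0

    if params.class_balance and fg.any() and (~fg).any():
        f = fg.mean()
        w = np.where(fg, 0.5 / f, 0.5 / (1.0 - f))
    else:
        w = np.ones(labels.shape, dtype=float)

    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size >= 2:
        # distance of each pixel to every object; keep the two smallest
        d1 = np.full(labels.shape, np.inf)
        d2 = np.full(labels.shape, np.inf)
        for obj in ids:
            d = ndimage.distance_transform_edt(labels != obj)
            closer = d < d1
            d2 = np.where(closer, d1, np.minimum(d2, d))
            d1 = np.where(closer, d, d1)
        border = params.w0 * np.exp(-((d1 + d2) ** 2) / (2.0 * params.sigma**2))
        w = w + border
    return w
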