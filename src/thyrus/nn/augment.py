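"""Training-time augmentation: random vertical flips and elastic deformation.

Elastic deformation follows the smoothed-random-displacement scheme: two
uniform(-1,1) fields are Gaussian-smoothed with σ = `elastic_sigma` pixels
and scaled by α = `elastic_alpha` pixels; image and mask are warped by the
same field (linear vs nearest interpolation) so labels stay aligned and
binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentParams", "augment"]


@dataclass(frozen=True)
class AugmentParams:
    vflip_prob: float = 0.5
    elastic_alpha: float = 10.0   # px
    elastic_sigma: float = 4.0    # px
    elastic_prob: float = 0.5

    def __post_init__(self):
        if not (0 <= self.vflip_prob <= 1 and 0 <= self.elastic_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.elastic_alpha < 0 or self.elastic_sigma <= 0:
            raise ValueError("invalid elastic parameters")


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    params: AugmentParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/deformation draw to an (H, W) slice and its mask."""
    params = params or AugmentParams()
    rng = rng or np.random.default_rng(0)
    img = np.asarray(image, dtype=np.float32)
    msk = np.asarray(mask, dtype=np.float32)
    if img.shape != msk.shape:
        raise ValueError("image and mask shapes differ")

    if rng.random() < params.vflip_prob:
        img = img[::-1].copy()
        msk = msk[::-1].copy()

    if params.elastic_alpha > 0 and rng.random() < params.elastic_prob:
        h, w = img.shape
        dr = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), params.elastic_sigma) * params.elastic_alpha
        dc = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), params.elastic_sigma) * params.elastic_alpha
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([rr + dr, cc + dc])
        img = ndimage.map_coordinates(img, coords, order=1, mode="reflect").astype(np.float32)
        msk = ndimage.map_coordinates(msk, coords, order=0, mode="reflect").astype(np.float32)

    return img, (msk > 0.5).astype(np.float32)
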