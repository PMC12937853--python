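"""Training-time augmentation: random rotation (+-15 deg), horizontal
flip (p = 0.5) and elastic deformation (alpha = 800, sigma = 20).

The same geometric transform is applied to the image (linear
interpolation) and the mask (nearest neighbour), so no new label values
can appear and image/mask registration is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, rotate

from .phantom import ImageSample


@dataclass
class AugmentConfig:
    rotation_deg: float = 15.0
    hflip_prob: float = 0.5
    elastic_alpha: float = 800.0
    elastic_sigma: float = 20.0
    enabled: bool = True

    def __post_init__(self):
        for f in ("rotation_deg", "hflip_prob", "elastic_alpha", "elastic_sigma"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")


def rotate_sample(sample: ImageSample, angle_deg: float) -> ImageSample:
    img = rotate(sample.image, angle_deg, reshape=False, order=1,
                 mode="nearest")
    msk = rotate(sample.mask, angle_deg, reshape=False, order=0,
                 mode="nearest")
    return replace(sample, image=np.clip(img, 0, 1),
                   mask=msk.astype(sample.mask.dtype))


def hflip_sample(sample: ImageSample) -> ImageSample:
    return replace(sample, image=sample.image[:, ::-1].copy(),
                   mask=sample.mask[:, ::-1].copy())


def elastic_sample(sample: ImageSample, dy: np.ndarray, dx: np.ndarray
                   ) -> ImageSample:
    """Warp by an explicit displacement field (pixels)."""
    h, w = sample.image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    coords = [yy + dy, xx + dx]
    img = map_coordinates(sample.image, coords, order=1, mode="reflect")
    msk = map_coordinates(sample.mask, coords, order=0, mode="reflect")
    return replace(sample, image=np.clip(img, 0, 1),
                   mask=msk.astype(sample.mask.dtype))


def elastic_field(shape, alpha: float, sigma: float,
                  rng: np.random.Generator):
    """Smooth random displacement field (Simard-style): U(-1, 1) noise,
    Gaussian-filtered with `sigma`, scaled by `alpha`."""
    dy = gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    dx = gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    return dy, dx


def augment(sample: ImageSample, cfg: AugmentConfig,
            rng: np.random.Generator) -> ImageSample:
    """One random augmentation draw; seeded rng makes it reproducible."""
    if not cfg.enabled:
        return sample
    out = sample
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    if cfg.rotation_deg > 0:
        out = rotate_sample(out, angle)
    if rng.random() < cfg.hflip_prob:
        out = hflip_sample(out)
    if cfg.elastic_alpha > 0:
        dy, dx = elastic_field(out.image.shape, cfg.elastic_alpha,
                               cfg.elastic_sigma, rng)
        out = elastic_sample(out, dy, dx)
    return out
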