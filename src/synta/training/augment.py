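"""Training-time augmentation.

Geometric transforms (random 90-degree rotations) are applied consistently
to image, masks and weight map; photometric corruption (additive Gaussian
noise, Gaussian blur, brightness/contrast/saturation/hue jitter) touches the
RGB patch only.  Deterministic in the seed: every random parameter is drawn
in a fixed order regardless of which augmentations are enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color

__all__ = ["AugmentConfig", "augment_patch"]


@dataclass(frozen=True)
class AugmentConfig:
    rot90: bool = True
    noise_sigma: tuple[float, float] = (0.0, 8.0)  # 8-bit units
    blur_sigma: tuple[float, float] = (0.0, 1.0)  # px
    brightness: tuple[float, float] = (-18.0, 18.0)  # additive, 8-bit units
    contrast: tuple[float, float] = (0.85, 1.15)  # multiplicative about the mean
    saturation: tuple[float, float] = (0.8, 1.2)
    hue: tuple[float, float] = (-0.03, 0.03)  # fraction of the hue circle

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(
            rot90=False,
            noise_sigma=(0.0, 0.0),
            blur_sigma=(0.0, 0.0),
            brightness=(0.0, 0.0),
            contrast=(1.0, 1.0),
            saturation=(1.0, 1.0),
            hue=(0.0, 0.0),
        )


def augment_patch(
    rgb: np.ndarray,
    semantic: np.ndarray,
    instance: np.ndarray,
    weights: np.ndarray | None,
    seed: int,
    cfg: AugmentConfig = AugmentConfig(),
):
    """Return the augmented (rgb, semantic, instance, weights) tuple."""
    if not (rgb.shape[:2] == semantic.shape == instance.shape):
        raise ValueError("misaligned patch shapes")
    rng = np.random.default_rng(seed)
    # fixed draw order keeps the stream stable across configurations
    k = int(rng.integers(0, 4))
    noise = float(rng.uniform(*cfg.noise_sigma))
    blur = float(rng.uniform(*cfg.blur_sigma))
    bright = float(rng.uniform(*cfg.brightness))
    contrast = float(rng.uniform(*cfg.contrast))
    sat = float(rng.uniform(*cfg.saturation))
    hue = float(rng.uniform(*cfg.hue))

    if cfg.rot90 and k:
        rgb = np.rot90(rgb, k, axes=(0, 1)).copy()
        semantic = np.rot90(semantic, k).copy()
        instance = np.rot90(instance, k).copy()
        if weights is not None:
            weights = np.rot90(weights, k).copy()

    img = rgb.astype(np.float64)
    if hue != 0.0 or sat != 1.0:
        hsv = color.rgb2hsv(img / 255.0)
        hsv[..., 0] = (hsv[..., 0] + hue) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * sat, 0.0, 1.0)
        img = color.hsv2rgb(hsv) * 255.0
    if contrast != 1.0:
        img = img.mean() + contrast * (img - img.mean())
    if bright != 0.0:
        img = img + bright
    if blur > 0.0:
        for ch in range(3):
            img[..., ch] = ndi.gaussian_filter(img[..., ch], blur)
    if noise > 0.0:
        img = img + rng.normal(0.0, noise, size=img.shape)
    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return rgb, semantic, instance, weights
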