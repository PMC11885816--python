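"""Automated post-processing of fiber probability maps.

Re-implements the fixed morphological pipeline applied downstream of the
segmentation network:

1. ``binarize_probability`` — scale the fiber probability map to [0, 255]
   and threshold at 210 (inclusive).
2. ``filter_objects`` — drop components smaller than a minimum object size
   (default 150 µm², the particle-size convention) or with circularity below
   0.1; the survivor is the "post processed" mask.
3. ``build_muscle_mask`` — whole-slice mask: ten 3x3 dilations followed by
   ten erosions (iterated closing), area opening at 3500 px², then a
   1,500,000 µm² size filter.
4. ``restrict_to_mask`` — clip the fiber mask to the muscle slice.
5. ``shape_filter`` — keep components with circularity in [0.35, 0.95]
   (pathologically relevant fibers only).
6. ``connective_tissue`` — muscle mask minus fibers, with fraction and area.

Circularity is 4*pi*area/perimeter² with the Crofton multi-direction
perimeter estimator, clipped to <= 1.  Connectivity is 8-connected
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

__all__ = [
    "PostprocessParams",
    "binarize_probability",
    "circularity",
    "filter_objects",
    "build_muscle_mask",
    "restrict_to_mask",
    "shape_filter",
    "connective_tissue",
    "postprocess_pipeline",
]

_S8 = np.ones((3, 3), dtype=bool)  # 8-connected structuring element


@dataclass(frozen=True)
class PostprocessParams:
    prob_threshold_8bit: int = 210
    min_object_area_um2: float = 150.0
    min_circularity_raw: float = 0.1
    shape_circ_min: float = 0.35
    shape_circ_max: float = 0.95
    closing_iterations: int = 10
    area_opening_px2: int = 3500
    muscle_mask_min_area_um2: float = 1_500_000.0
    pixel_size_um: float = 0.6615

    def __post_init__(self) -> None:
        if not (0 <= self.min_circularity_raw <= 1 and 0 <= self.shape_circ_min < self.shape_circ_max <= 1):
            raise ValueError("circularity thresholds must lie in [0, 1] with min < max")
        if min(self.min_object_area_um2, self.muscle_mask_min_area_um2, self.pixel_size_um) <= 0:
            raise ValueError("areas and pixel size must be positive")


def binarize_probability(fiber_prob: np.ndarray, p: PostprocessParams) -> np.ndarray:
    """mask = round(prob * 255) >= threshold (inclusive, 8-bit convention)."""
    prob = np.asarray(fiber_prob, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    return np.round(prob * 255.0) >= p.prob_threshold_8bit


def circularity(component: np.ndarray) -> float:
    """4*pi*A/P² of one binary component, Crofton perimeter, clipped to 1."""
    comp = np.asarray(component, dtype=bool)
    area = int(comp.sum())
    if area == 0:
        raise ValueError("empty component")
    if area == 1:
        return 1.0
    perim = measure.perimeter_crofton(comp, directions=4)
    if perim == 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area / perim**2))


def _component_slices(mask: np.ndarray):
    labels, n = ndi.label(mask, structure=_S8)
    slices = ndi.find_objects(labels)
    for k, sl in enumerate(slices, start=1):
        yield k, sl, labels[sl] == k
    return


def _keep_components(mask: np.ndarray, keep_fn) -> np.ndarray:
    labels, n = ndi.label(mask, structure=_S8)
    out = np.zeros_like(mask, dtype=bool)
    for k, sl in enumerate(ndi.find_objects(labels), start=1):
        comp = labels[sl] == k
        if keep_fn(comp):
            out[sl] |= comp
    return out


def filter_objects(mask: np.ndarray, p: PostprocessParams) -> np.ndarray:
    """Remove components below the size floor or the raw circularity floor."""
    px_area = p.pixel_size_um**2

    def keep(comp: np.ndarray) -> bool:
        if comp.sum() * px_area < p.min_object_area_um2:
            return False
        return circularity(comp) >= p.min_circularity_raw

    return _keep_components(np.asarray(mask, dtype=bool), keep)


def build_muscle_mask(postprocessed: np.ndarray, p: PostprocessParams) -> np.ndarray:
    """Whole-slice mask: iterated closing, area opening, then size filter."""
    mask = np.asarray(postprocessed, dtype=bool)
    if not mask.any():
        return mask.copy()
    # pad so the dilation is never clipped at the window edge: the result is
    # the infinite-plane closing restricted to the image, extensive everywhere
    n_it = p.closing_iterations
    padded = np.pad(mask, n_it)
    closed = ndi.binary_dilation(padded, structure=_S8, iterations=n_it)
    closed = ndi.binary_erosion(closed, structure=_S8, iterations=n_it)
    closed = closed[n_it:-n_it, n_it:-n_it]
    # area opening: components up to the given size are removed
    closed = _keep_components(closed, lambda comp: comp.sum() > p.area_opening_px2)
    px_area = p.pixel_size_um**2
    return _keep_components(
        closed, lambda comp: comp.sum() * px_area >= p.muscle_mask_min_area_um2
    )


def restrict_to_mask(fiber_mask: np.ndarray, muscle_mask: np.ndarray) -> np.ndarray:
    if fiber_mask.shape != muscle_mask.shape:
        raise ValueError("misaligned masks")
    return np.asarray(fiber_mask, bool) & np.asarray(muscle_mask, bool)


def shape_filter(postprocessed: np.ndarray, p: PostprocessParams) -> np.ndarray:
    """Keep components with circularity in [shape_circ_min, shape_circ_max]."""

    def keep(comp: np.ndarray) -> bool:
        c = circularity(comp)
        return p.shape_circ_min <= c <= p.shape_circ_max

    return _keep_components(np.asarray(postprocessed, dtype=bool), keep)


def connective_tissue(
    muscle_mask: np.ndarray, fiber_mask: np.ndarray, pixel_size_um: float
):
    """(ct mask, ct fraction of the muscle area, ct area in µm²)."""
    muscle = np.asarray(muscle_mask, bool)
    fiber = np.asarray(fiber_mask, bool)
    n_muscle = int(muscle.sum())
    if n_muscle == 0:
        raise ValueError("empty muscle mask: connective-tissue fraction undefined")
    ct = muscle & ~fiber
    n_ct = int(ct.sum())
    return ct, n_ct / n_muscle, n_ct * pixel_size_um**2


def postprocess_pipeline(fiber_prob: np.ndarray, p: PostprocessParams) -> dict:
    """Run the full fixed-order pipeline on one probability map.

    Returns a dict with the raw, post-processed, muscle, restricted,
    shape-filtered and connective-tissue masks plus CT summary numbers.
    """
    raw = binarize_probability(fiber_prob, p)
    post = filter_objects(raw, p)
    muscle = build_muscle_mask(post, p)
    segmentation = restrict_to_mask(post, muscle)
    shaped = shape_filter(segmentation, p)
    out = {
        "raw": raw,
        "postprocessed": post,
        "muscle_mask": muscle,
        "segmentation": segmentation,
        "shape_filter": shaped,
    }
    if muscle.any():
        ct, frac, area = connective_tissue(muscle, segmentation, p.pixel_size_um)
        out.update({"connective_tissue": ct, "ct_fraction": frac, "ct_area_um2": area})
    return out
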