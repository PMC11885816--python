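"""Per-pixel loss weights emphasizing inter-fiber borders.

The weight at pixel x is

    w(x) = wc(class(x)) + w0 * exp(-(d1(x) + d2(x))^2 / (2 sigma^2))

where d1/d2 are the Euclidean distances (in px) to the nearest and
second-nearest distinct fiber instance.  The exponential term is ~w0 on the
thin ridge between two touching fibers (where d1 + d2 is the gap width) and
vanishes elsewhere; the class term wc compensates class imbalance.  Defaults
follow the tuned recipe: very high border amplitude w0 = 400 with sigma = 5
px, fiber-body factor 50, background factor 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["WeightMapParams", "compute_weight_map"]


@dataclass(frozen=True)
class WeightMapParams:
    w0: float = 400.0
    sigma_px: float = 5.0
    w_fiber: float = 50.0
    w_background: float = 10.0
    # the border emphasis for boundary pixels comes from the w0 term, which
    # peaks exactly there; their class factor matches the background's
    w_boundary: float = 10.0

    def __post_init__(self) -> None:
        if min(self.w0, self.sigma_px, self.w_fiber, self.w_background, self.w_boundary) <= 0:
            raise ValueError("all weight-map parameters must be strictly positive")


def compute_weight_map(
    instance_map: np.ndarray,
    semantic_mask: np.ndarray,
    p: WeightMapParams = WeightMapParams(),
) -> np.ndarray:
    """Weight field over all pixels; O(K) distance transforms, O(1) memory in K."""
    if instance_map.shape != semantic_mask.shape:
        raise ValueError("instance_map and semantic_mask shapes differ")
    wc_table = np.array([p.w_background, p.w_fiber, p.w_boundary], dtype=np.float64)
    w = wc_table[semantic_mask.astype(np.intp)]

    ids = np.unique(instance_map[instance_map > 0])
    if ids.size >= 2:
        d1 = np.full(instance_map.shape, np.inf)
        d2 = np.full(instance_map.shape, np.inf)
        for k in ids:
            d = ndi.distance_transform_edt(instance_map != k)
            closer = d < d1
            np.minimum(d2, d, out=d2)
            d2[closer] = d1[closer]
            d1[closer] = d[closer]
        w = w + p.w0 * np.exp(-((d1 + d2) ** 2) / (2.0 * p.sigma_px**2))
    return w
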