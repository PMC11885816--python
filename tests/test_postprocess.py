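"""Morphological post-processing pipeline: thresholds, filters, muscle mask."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from synta.postprocess import (
    PostprocessParams,
    binarize_probability,
    build_muscle_mask,
    circularity,
    connective_tissue,
    filter_objects,
    postprocess_pipeline,
    restrict_to_mask,
    shape_filter,
)


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = radius + pad
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


class TestBinarize:
    def test_threshold_arithmetic(self):
        p = PostprocessParams()
        prob = np.array([[0.9, 0.8, 0.0]])
        # round(0.9*255)=230 >= 210; round(0.8*255)=204 < 210
        assert binarize_probability(prob, p).tolist() == [[True, False, False]]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_probability(np.array([[1.2]]), PostprocessParams())


class TestCircularity:
    def test_disk_is_nearly_circular(self):
        assert circularity(disk_mask(30)) >= 0.9

    def test_thin_line_below_raw_threshold(self):
        line = np.zeros((5, 110), bool)
        line[2, 5:105] = True
        assert circularity(line) < 0.1

    def test_never_exceeds_one(self, rng):
        for _ in range(100):
            blob = rng.random((20, 20)) > 0.4
            blob = ndi.binary_closing(blob)
            if blob.any():
                assert circularity(blob) <= 1.0

    def test_single_pixel_defined_as_one(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert circularity(m) == 1.0


class TestFilterObjects:
    def test_hand_enumerated_survivors(self):
        """Components of area {100, 200, 2000} µm² with circularity
        {0.9, 0.05, 0.9}: only the large round one survives both rules."""
        px = 1.0  # 1 µm/px so px² = µm²
        mask = np.zeros((120, 260), bool)
        mask[10:20, 10:20] = True  # 100 µm² round-ish -> too small
        line = np.zeros_like(mask)
        line[60, 10:210] = True  # 200 µm² but circularity ~0.03 -> removed
        mask |= line
        mask[40:85, 215:260][disk_mask(20, 2)[:45, :45]] = True  # big disk survives
        big_area = disk_mask(20, 2)[:45, :45].sum()
        assert big_area * px**2 >= 150
        p = PostprocessParams(pixel_size_um=px)
        out = filter_objects(mask, p)
        n_components = ndi.label(out, structure=np.ones((3, 3)))[1]
        assert n_components == 1
        assert out.sum() == big_area

    def test_empty_mask(self):
        p = PostprocessParams()
        assert not filter_objects(np.zeros((8, 8), bool), p).any()

    def test_anti_extensive(self, rng):
        mask = rng.random((64, 64)) > 0.6
        out = filter_objects(mask, PostprocessParams(pixel_size_um=1.0))
        assert not (out & ~mask).any()


class TestMuscleMask:
    def test_closing_bridges_15px_gap(self):
        """x10 dilation with a 3x3 SE bridges gaps up to 20 px, so two blobs
        15 px apart fuse into one component."""
        mask = np.zeros((200, 300), bool)
        mask[50:150, 40:140] = True
        mask[50:150, 155:255] = True  # gap of 15 px
        p = PostprocessParams(pixel_size_um=10.0)  # generous size filters pass
        out = build_muscle_mask(mask, p)
        assert ndi.label(out, structure=np.ones((3, 3)))[1] == 1

    def test_closing_is_extensive(self, rng):
        mask = ndi.binary_dilation(rng.random((100, 100)) > 0.95, iterations=2)
        p = PostprocessParams(
            pixel_size_um=1000.0, area_opening_px2=0, muscle_mask_min_area_um2=1e-9
        )
        out = build_muscle_mask(mask, p)
        assert (out | mask).sum() == out.sum()  # out ⊇ mask

    def test_area_opening_removes_small_components(self):
        mask = np.zeros((300, 300), bool)
        mask[10:60, 10:60] = True  # 2500 px² <= 3500 -> removed
        mask[100:200, 100:200] = True  # 10000 px² -> kept
        p = PostprocessParams(pixel_size_um=100.0)
        out = build_muscle_mask(mask, p)
        labels, n = ndi.label(out, structure=np.ones((3, 3)))
        assert n == 1
        assert out[150, 150] and not out[30, 30]

    def test_final_size_filter_depends_on_pixel_size(self):
        mask = np.zeros((520, 520), bool)
        mask[10:510, 10:510] = True  # 500x500 px blob
        removed = build_muscle_mask(mask, PostprocessParams(pixel_size_um=2.0))
        # closing grows the blob, so compare against the closed area:
        # 250,000 px² x 4 µm² = 1,000,000 µm² < 1,500,000 -> dropped
        assert not removed.any()
        kept = build_muscle_mask(mask, PostprocessParams(pixel_size_um=3.0))
        assert kept.any()


class TestRestrictAndCT:
    def test_restrict_identity_and_empty(self):
        fiber = np.eye(8, dtype=bool)
        assert np.array_equal(restrict_to_mask(fiber, np.ones((8, 8), bool)), fiber)
        assert not restrict_to_mask(fiber, np.zeros((8, 8), bool)).any()

    def test_ct_arithmetic(self):
        muscle = np.zeros((200, 100), bool)
        muscle.ravel()[:10_000] = True
        fiber = np.zeros_like(muscle)
        fiber.ravel()[:7_500] = True
        ct, frac, area = connective_tissue(muscle, fiber, pixel_size_um=0.5)
        assert frac == pytest.approx(0.25)
        assert area == pytest.approx(625.0)

    def test_ct_degenerate_cases(self):
        muscle = np.ones((10, 10), bool)
        _, frac, _ = connective_tissue(muscle, muscle, 1.0)
        assert frac == 0.0
        _, frac, _ = connective_tissue(muscle, np.zeros_like(muscle), 1.0)
        assert frac == 1.0
        with pytest.raises(ValueError):
            connective_tissue(np.zeros((5, 5), bool), np.zeros((5, 5), bool), 1.0)


class TestShapeFilter:
    def test_removes_near_perfect_disk_and_line(self):
        p = PostprocessParams()
        d = disk_mask(30)
        assert circularity(d) > 0.95  # precondition: disk above the cap
        assert not shape_filter(d, p).any()
        line = np.zeros((5, 110), bool)
        line[2, 5:105] = True
        assert not shape_filter(line, p).any()

    def test_keeps_irregular_blob(self):
        # dumbbell: two disks joined by a bar -> mid-range circularity (~0.5)
        blob = np.zeros((60, 120), bool)
        d = disk_mask(15, pad=2)
        blob[13 : 13 + d.shape[0], 5 : 5 + d.shape[1]] |= d
        blob[13 : 13 + d.shape[0], 55 : 55 + d.shape[1]] |= d
        blob[24:36, 20:70] = True
        c = circularity(blob)
        assert 0.35 <= c <= 0.95
        assert shape_filter(blob, PostprocessParams()).any()


def test_end_to_end_pipeline_survivor_count():
    """Hand-enumerated toy probability map through the full fixed-order
    pipeline: two valid fibers survive, the low-probability blob, the tiny
    speck and the thin line do not."""
    px = 2.0
    prob = np.zeros((420, 420))
    d30 = disk_mask(30)
    prob[10 : 10 + d30.shape[0], 10 : 10 + d30.shape[1]][d30] = 0.95  # fiber A... circ>0.95 though
    sq = np.s_[200:280, 40:140]
    prob[sq] = 0.9  # rectangle: circularity ~0.78, survives shape filter
    prob[300:370, 200:290] = 0.9  # rectangle B survives
    prob[50:60, 300:310] = 0.7  # below the 210/255 threshold -> gone at step 1
    prob[120, 340:400] = 0.95  # thin line -> killed by raw circularity 0.1? (c~0.05)
    prob[390:392, 10:13] = 0.95  # 6 px -> 24 µm² < 150 µm² -> size filter

    p = PostprocessParams(pixel_size_um=px, muscle_mask_min_area_um2=100.0)
    res = postprocess_pipeline(prob, p)
    # raw mask: everything >= 210/255
    assert not res["raw"][55, 305]
    # post-processed: line and speck removed, disk + rectangles stay
    n_post = ndi.label(res["postprocessed"], structure=np.ones((3, 3)))[1]
    assert n_post == 3
    # shape filter: near-perfect disk (circ > 0.95) removed, rectangles kept
    n_shape = ndi.label(res["shape_filter"], structure=np.ones((3, 3)))[1]
    assert n_shape == 2
    # CT = muscle minus fibers is consistent
    if "connective_tissue" in res:
        assert not (res["connective_tissue"] & res["segmentation"]).any()
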