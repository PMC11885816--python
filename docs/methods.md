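# Methods

This note documents the models and procedures implemented in `synta`, the
defaults chosen where the design was open, and what the synthetic data does
and does not establish about real tissue.

## 1. Procedural tissue model

### Noise primitives

All geometry and texture derive from two seedable primitives
(`synta.noise`). Feature points and lattice values are produced lazily by a
SplitMix64 hash of `(cell index, seed)`, so every field is unbounded,
seekable, and bitwise reproducible; no point lists are stored.

**Worley (cellular) noise.** One feature point per lattice cell of side
`1/√density`, displaced from the cell center by `jitter ∈ [0, 1]` times a
uniform offset (the point never leaves its cell). For a query point, `f1`
and `f2` are the Euclidean distances to the nearest and second-nearest
feature points and `owner` identifies the nearest one. The implementation
scans a 5×5 cell neighborhood: a 3×3 scan is not provably exact for `f2` at
high jitter, while the residual failure mass of 5×5 versus an exhaustive
scan is negligible (and is tested against a 7×7 exhaustive oracle on random
configurations).

**Fractal value noise (fBm).** Smoothstep-interpolated lattice hashes summed
over octaves (wavelength halves, amplitude × persistence per octave),
normalized so the range [0, 1] is exact. Chosen for all non-cellular
textures (stain variation, domain warp) as the cheapest smooth noise that
suffices for low-frequency texture; gradient-noise variants would change
nothing downstream.

**Domain warping** displaces query coordinates by `amplitude · (2·fBm − 1)`
per axis (two independent streams). Warping the Worley queries turns
polygonal cells into the organic fiber outlines seen in sections; amplitude
defaults to 15 % of the nominal fiber diameter.

### Scene assembly

A scene is generated in five pure stages (`synta.simulator`):

1. **Parameter sampling.** All geometric parameters are configured in µm as
   *ranges*; one uniform draw per image. The per-image pixel size (µm/px) is
   drawn from a normal law truncated to (0.2, 1.6) µm/px whose *truncated*
   moments are calibrated to exactly 0.79 ± 0.22 µm/px — the reported spread
   is a property of the dataset, so the inner parameters absorb the
   truncation bias (a ~1.5 % SD effect).
2. **Tessellation.** Fine Worley partition with lattice spacing equal to the
   drawn nominal fiber diameter (in px); boundary pixels where
   `f2 − f1 < max(endomysium_px, 1.5)` (the 1.5 px floor guarantees the
   3-class target always has a non-empty boundary class and instances can
   never touch across the band), plus perimysium bands from a coarse Worley
   partition at fascicle scale. Instances are 8-connected components of the
   remaining pixels, relabeled contiguously; components below
   `max(16 px², 2 % of a nominal cell)` are merged into boundary. By
   construction two distinct instance ids are never 8-adjacent.
3. **Nuclei.** Peripheral nuclei: per fiber, a Poisson count with mean
   `rate × boundary length / 100 µm`, positioned on boundary-adjacent fiber
   pixels, elliptical, major axis tangent to the fiber outline (perpendicular
   to the distance-transform gradient). Central nuclei — a myopathic cue —
   appear per fiber with a configurable probability (default 0.05).
4. **Rendering.** Per-image base colors are drawn from 8-bit per-channel
   intervals (eosin-pink fibers, paler connective tissue, dark blue-purple
   nuclei with a darker rim, near-white background); intra-fiber and
   connective textures modulate the base color by the fBm field scaled by
   `stain_texture_amplitude` (0 renders piecewise-constant). Gaussian blur
   then additive Gaussian noise model optics and sensor.
5. **Artifacts.** Freezing-type holes (Poisson per mm² of fiber area, 3–9 µm)
   and, with probability 0.2, one ragged pale crack polyline. Artifacts
   corrupt the *appearance only*: masks are never modified, so a model
   trained on these images must recognize fibers through artifacts — this is
   what makes the trained network robust to real freezing artifacts.

### Default calibration

Defaults emulate normal murine skeletal muscle at the reference corpus
geometry (120 images of 2048², 0.79 ± 0.22 µm/px, ≈ 74 k fibers total,
i.e. ≈ 620 instances per image). The free knob is the nominal fiber-diameter
range; (65, 96.5) µm puts the per-image instance count at ≈ 580 at the mean
pixel size and ≈ 620 under the full pixel-size law (the count scales with
the *squared* pixel size, so the law mean exceeds the fixed-pixel-size
mean by E[px²]/0.79² ≈ 1.08). Endomysium (3.5–7 µm) and perimysium
(5–12 µm widths at 300–520 µm fascicle scale) set the boundary-class share
so the fiber class covers ≈ 80 % of pixels. Per-image instance counts under
the pixel-size law have SD ≈ 330 — dominated by the px² factor — so
small-subset estimates of the corpus total carry a proportionally large
standard error; this is a property of the stated generation conditions, not
of the estimator.

## 2. Training harness

**Weight map.** `w(x) = wc(class(x)) + w0·exp(−(d1(x)+d2(x))²/(2σ²))` with
`d1`, `d2` the distances to the two nearest distinct fiber instances,
computed for all pixels by K distance transforms with a running two-smallest
update (O(K) time, O(1) memory in K). Defaults: `w0 = 400`, `σ = 5 px`,
`wc` = 50 (fiber), 10 (background), 10 (boundary). The boundary class keeps
`wc = 10` because the exponential term already peaks exactly on boundary
ridges; the published factors name only fibers and background. The additive
`wc` reading follows the weight-map formulation this recipe cites.

**Augmentation.** Random 90° rotations applied consistently to image, masks
and weights; additive noise, blur, brightness/contrast/saturation/hue jitter
on RGB only. All random parameters are drawn in a fixed order so the stream
is stable across configurations.

**Network.** Classic U-shaped encoder–decoder: per level two 3×3
convolutions + group normalization + ReLU, 2×2 max-pool down, bilinear 2×
upsampling and skip concatenation up, 1×1 head, three classes (background /
fiber / boundary). Implemented self-contained in numpy (im2col convolutions,
exact adjoint of the bilinear upsampler, Adam), with gradients verified
against finite differences. The full-scale preset mirrors the published
recipe — depth 4, 64 base channels, 120 epochs × 150 iterations, batch 1,
400 px patches, Adam at 10⁻³; the learning-rate decay family is not
published, so a single ×0.1 step at ⅔ of the epochs is used. The smoke
preset (depth 2, 8 channels, 3 epochs × 20 iterations, 128 px patches)
trains on one CPU in under a minute and is what the test suite exercises;
the full preset exists as configuration but is not run in tests.

**Normalization** is per-image channelwise standardization, applied once per
image (before tiling at inference, so tiled and whole-image predictions see
identical inputs).

**Model selection** evaluates every per-epoch checkpoint by mean fiber-class
F1 on validation patches and returns the argmax (ties to the later epoch).
Validation uses held-out *synthetic* patches — the original selection scheme
scored real stained patches, which cannot ship with this package; this is
the one deliberate deviation and it changes the selection criterion's data,
not its logic.

**Inference** is overlap-tiled (default tile 400 px, overlap 100 px) with
tapered blending that down-weights tile borders (central-crop style); group
normalization makes predictions mildly window-dependent, which the taper and
the per-image standardization keep below a 0.02 mean absolute probability
difference against whole-image inference for a trained model.

**Metrics.** Pixelwise accuracy/precision/recall/F1 on the fiber class
(empty-vs-empty defined as 1.0). Instance AP = TP/(TP+FP+FN) after greedy
one-to-one matching by descending IoU (pairs match when IoU ≥ threshold),
over thresholds 0.5 … 1.0 in 0.05 steps; the matcher is unspecified in the
original description and greedy matching is the common choice at these
segmentation qualities.

## 3. Post-processing

Fixed order: binarize → object filter → muscle mask → restrict → shape
filter / connective tissue.

- Binarization: `round(p·255) ≥ 210` (inclusive, 8-bit convention).
- Object filter: remove 8-connected components with area < 150 µm² or
  circularity < 0.1. The published size floor of "150 µm" is ambiguous
  between a length and an area; the area reading (the particle-size
  convention) is the default because a 150 µm *diameter* floor would delete
  exactly the small diseased fibers the analysis targets. Both readings are
  configurable.
- Muscle mask: ×10 dilation then ×10 erosion with the 3×3 (8-connected)
  element, computed on a padded canvas so it equals the algebraic closing
  (extensive everywhere, including image borders); then remove components
  with area ≤ 3500 px² ("area opening", read as removing components up to
  the given size, acting on foreground); then keep components ≥ 1.5·10⁶ µm².
- Circularity: `4πA/P²` with the Crofton 4-direction perimeter, clipped to
  ≤ 1; single-pixel components are defined as 1.0. Crofton is the closest
  widely reproducible analogue of the weighted perimeter used by the
  original toolset; circularities are reproducible bit-for-bit within this
  package but can differ from other tools in the second decimal.
- Shape filter: keep circularity ∈ [0.35, 0.95] — removes both debris and
  suspiciously perfect disks, leaving diagnostically relevant fibers.
- Connective tissue: `muscle ∧ ¬fiber`; fraction and µm² area measured
  inside the muscle mask (empty muscle mask is a signalled error).

## 4. Morphometry

- **Fiber diameter** defaults to the minimum Feret diameter — the standard
  myofiber size measure, robust to oblique sectioning — computed exactly by
  rotating calipers over the convex hull of pixel-corner points (the minimum
  width of a convex polygon is attained flush against a hull edge).
  Equivalent diameter `2√(A/π)` is available as an alternative; reference
  statistics always record which measure they used.
- **Local thickness** (largest inscribed disk): for distance-transform
  values in descending order, every pixel covered by the disk of that radius
  receives diameter `2·EDT − 1` unless a larger disk already claimed it. The
  −1 accounts for the boundary lying half a pixel beyond the nearest
  background pixel center on each side; covering disks keep radius EDT
  because pixels are unit squares. A rasterized radius-r disk then reads
  `2r ± 1` everywhere and an n-px band reads n. Exact mode is intended for
  masks up to ~1k²; larger masks should be processed in tiles or
  downsampled.
- **Reference statistics**: per-region mean and sample SD (ddof = 1) of the
  configured diameter measure over healthy-control records; regions are
  assigned by centroid membership in an optional region mask (no mask →
  whole-section statistics).
- **Abnormality**: a fiber is abnormal iff `|d − µ_region| > 2σ_region`
  (strict), split into `small`/`large`. Under an in-distribution normal law
  this flags `2Φ(−2) ≈ 4.55 %` of fibers, which the tests verify on 10⁵
  draws.

## 5. What the synthetic data does not show

The generator reproduces the *geometry and appearance statistics* of H&E
muscle cross-sections, not their biology: no fiber-type heterogeneity, no
longitudinal or oblique sections, no physically based light transport, no
staining chemistry, and artifacts are stylized. Passing tests therefore
demonstrate internal consistency (the pipeline measures what the generator
put in) and algorithmic correctness against closed forms and brute-force
oracles — not performance on real slides. The problem sizes exercised in
the test suite (256² training images, a reduced network, 12 full-size
scenes for dataset statistics) are chosen so the whole suite runs on one
CPU in minutes; all full-scale settings remain available as configuration.

## 6. Numerical conventions

- Coordinates are (row, col), 0-based, pixel centers at integers; µm enters
  only through `pixel_size_um`.
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  per-image seeds are SplitMix64 hashes of (master seed, index), so any
  image can be regenerated independently and whole datasets are
  byte-identical across runs.
- 8-connectivity everywhere (components, structuring elements).
- Degenerate conventions: empty ground truth with empty prediction scores
  1.0; a single-fiber section reports SD 0 with an explicit flag; empty
  masks raise rather than return NaN.
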