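"""Dataset orchestration and on-disk formats.

A dataset is a directory of per-image triplets (RGB PNG, 16-bit instance
TIFF, 8-bit semantic PNG) plus a CSV manifest and the resolved configuration
as JSON.  Per-image seeds are derived from ``(master_seed, index)`` with a
stable integer hash, so any image can be regenerated independently and the
whole dataset is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .noise import _splitmix64
from .simulator import RenderedSample, SceneConfig, SceneParams, make_sample

__all__ = [
    "DatasetManifest",
    "stable_seed",
    "generate_dataset",
    "read_sample",
    "sample_patches",
    "make_fixture",
]

# reference synthetic-corpus geometry: 120 images of 2048 x 2048 px
DEFAULT_N_IMAGES = 120
DEFAULT_IMAGE_SIZE = 2048

MANIFEST_COLUMNS = [
    "index",
    "rgb_file",
    "instance_file",
    "semantic_file",
    "seed",
    "pixel_size_um",
    "fiber_count",
]


def stable_seed(master_seed: int, index: int) -> int:
    """Reproducible 31-bit per-image seed from (master_seed, index)."""
    h = _splitmix64(np.uint64((master_seed & 0xFFFFFFFFFFFFFFFF)) ^ _splitmix64(np.uint64(index)))
    return int(h & np.uint64(0x7FFFFFFF))


@dataclass
class DatasetManifest:
    frame: pd.DataFrame  # one row per image, MANIFEST_COLUMNS
    master_seed: int
    config: SceneConfig
    root: Path

    @property
    def n_images(self) -> int:
        return len(self.frame)

    @property
    def total_fibers(self) -> int:
        return int(self.frame["fiber_count"].sum())

    def save(self) -> None:
        self.frame.to_csv(self.root / "manifest.csv", index=False)
        meta = {"master_seed": self.master_seed, "scene_config": self.config.to_dict()}
        (self.root / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, root: Path | str) -> "DatasetManifest":
        root = Path(root)
        frame = pd.read_csv(root / "manifest.csv")
        meta = json.loads((root / "config.json").read_text())
        return cls(
            frame=frame,
            master_seed=int(meta["master_seed"]),
            config=SceneConfig.from_dict(meta["scene_config"]),
            root=root,
        )


def write_sample(sample: RenderedSample, root: Path, index: int) -> dict:
    """Write one sample's triplet losslessly; returns its manifest row."""
    root = Path(root)
    rgb_file = f"image_{index:04d}.png"
    inst_file = f"instance_{index:04d}.tif"
    sem_file = f"semantic_{index:04d}.png"
    iio.imwrite(root / rgb_file, sample.rgb)
    # 16-bit container for per-image ids (~650 fibers/image); lossless 32-bit
    # fallback for id counts beyond the 16-bit range
    inst_dtype = np.uint16 if sample.instance_map.max() <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(root / inst_file, sample.instance_map.astype(inst_dtype))
    iio.imwrite(root / sem_file, sample.semantic_mask.astype(np.uint8))
    (root / f"params_{index:04d}.json").write_text(json.dumps(sample.params.to_dict(), indent=2))
    return {
        "index": index,
        "rgb_file": rgb_file,
        "instance_file": inst_file,
        "semantic_file": sem_file,
        "seed": sample.params.seed,
        "pixel_size_um": sample.pixel_size_um,
        "fiber_count": sample.n_fibers,
    }


def generate_dataset(
    cfg: SceneConfig,
    n_images: int,
    shape: tuple[int, int],
    master_seed: int,
    outdir: Path | str,
) -> DatasetManifest:
    """Render ``n_images`` scenes and write the full dataset to ``outdir``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        sample = make_sample(cfg, shape, stable_seed(master_seed, i))
        rows.append(write_sample(sample, outdir, i))
    manifest = DatasetManifest(
        frame=pd.DataFrame(rows, columns=MANIFEST_COLUMNS),
        master_seed=master_seed,
        config=cfg,
        root=outdir,
    )
    manifest.save()
    return manifest


def read_sample(manifest: DatasetManifest, index: int) -> RenderedSample:
    """Load one sample back; round-trip with :func:`write_sample` is lossless."""
    row = manifest.frame.loc[manifest.frame["index"] == index]
    if row.empty:
        raise KeyError(f"index {index} not in manifest")
    row = row.iloc[0]
    root = manifest.root
    for col in ("rgb_file", "instance_file", "semantic_file"):
        if not (root / row[col]).exists():
            raise FileNotFoundError(root / row[col])
    rgb = iio.imread(root / row["rgb_file"])
    inst = tifffile.imread(root / row["instance_file"]).astype(np.int32)
    sem = iio.imread(root / row["semantic_file"])
    if not set(np.unique(sem)) <= {0, 1, 2}:
        raise ValueError(f"{row['semantic_file']}: semantic classes outside {{0,1,2}}")
    raw = json.loads((root / f"params_{index:04d}.json").read_text())
    params = SceneParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
    return RenderedSample(
        rgb=rgb,
        instance_map=inst,
        semantic_mask=sem.astype(np.uint8),
        params=params,
        pixel_size_um=float(row["pixel_size_um"]),
    )


def sample_patches(
    samples: "list[RenderedSample] | DatasetManifest",
    patch_size: int,
    n: int,
    seed: int,
):
    """Yield ``n`` uniformly random, fully-inside (rgb, semantic, instance) patches."""
    rng = np.random.default_rng(seed)
    if isinstance(samples, DatasetManifest):
        loaded = [read_sample(samples, int(i)) for i in samples.frame["index"]]
    else:
        loaded = list(samples)
    if not loaded:
        raise ValueError("no images to sample from")
    for s in loaded:
        if patch_size > min(s.rgb.shape[:2]):
            raise ValueError("patch_size larger than image")
    for _ in range(n):
        s = loaded[rng.integers(0, len(loaded))]
        h, w = s.rgb.shape[:2]
        r = int(rng.integers(0, h - patch_size + 1))
        c = int(rng.integers(0, w - patch_size + 1))
        yield (
            s.rgb[r : r + patch_size, c : c + patch_size],
            s.semantic_mask[r : r + patch_size, c : c + patch_size],
            s.instance_map[r : r + patch_size, c : c + patch_size],
        )


def _degenerate_params(seed: int, pixel_size_um: float = 0.79) -> SceneParams:
    return SceneParams(
        seed=seed,
        pixel_size_um=pixel_size_um,
        fiber_diameter_um=85.0,
        endomysium_thickness_um=4.0,
        fascicle_diameter_um=400.0,
        perimysium_width_um=8.0,
        nuclei_per_perimeter=0.0,
        central_nucleus_prob=0.0,
        nucleus_radius_um=3.0,
        hematoxylin_rgb=(76.0, 56.0, 130.0),
        eosin_fiber_rgb=(220.0, 150.0, 170.0),
        connective_rgb=(238.0, 198.0, 214.0),
        background_rgb=(247.0, 245.0, 247.0),
        stain_texture_amplitude=0.0,
        hole_artifact_density=0.0,
        crack_probability=0.0,
        blur_sigma=0.0,
        noise_sigma=0.0,
    )


def make_fixture(kind: str, seed: int = 0) -> RenderedSample:
    """Tiny deterministic scenes with analytically known ground truth.

    Kinds: ``regular_grid`` (unjittered, unwarped Worley -> square Voronoi
    cells), ``two_fibers``, ``empty_background``, ``single_disk`` (one
    radius-20 px disk instance).
    """
    params = _degenerate_params(seed)
    shape = (192, 192)
    if kind == "regular_grid":
        from .simulator import build_fiber_tessellation, render_he

        params = _degenerate_params(seed, pixel_size_um=1.0)
        inst, boundary = build_fiber_tessellation(
            params, shape, warp_amplitude_frac=0.0, jitter=0.0
        )
        rgb = render_he(inst, boundary, [], params, seed)
    elif kind == "two_fibers":
        inst = np.zeros(shape, dtype=np.int32)
        inst[20:90, 30:160] = 1
        inst[100:170, 30:160] = 2
        boundary = ~(inst > 0)
        from .simulator import render_he

        rgb = render_he(inst, boundary, [], params, seed)
    elif kind == "empty_background":
        inst = np.zeros(shape, dtype=np.int32)
        boundary = np.zeros(shape, dtype=bool)
        rgb = np.full(shape + (3,), 247, dtype=np.uint8)
    elif kind == "single_disk":
        inst = np.zeros(shape, dtype=np.int32)
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        disk = (rr - 96) ** 2 + (cc - 96) ** 2 <= 20**2
        inst[disk] = 1
        boundary = ~disk
        from .simulator import render_he

        rgb = render_he(inst, boundary, [], params, seed)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")

    semantic = np.zeros(shape, dtype=np.uint8)
    semantic[inst > 0] = 1
    semantic[(inst == 0) & boundary] = 2
    return RenderedSample(
        rgb=rgb,
        instance_map=inst,
        semantic_mask=semantic,
        params=params,
        pixel_size_um=params.pixel_size_um,
    )
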