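"""Encoder-decoder segmentation network, training loop and inference.

The network follows the classic U-shaped topology (two 3x3 conv + group
norm + ReLU per level, 2x2 max pooling down, bilinear upsampling and skip
concatenation up, 1x1 output head) predicting three classes: background,
fiber and boundary.  The full-scale preset mirrors the published recipe
(depth 4, 64 base channels, 120 epochs x 150 iterations, batch 1, 400 px
patches, Adam at 1e-3 with step decay); the smoke preset is a reduced
configuration that trains to a useful fiber segmentation on synthetic data
in minutes on one CPU.

Training minimizes per-pixel weighted cross-entropy; the weight map is
computed on the fly per patch (see :mod:`synta.training.weights`), followed
by augmentation and per-image channelwise standardization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..dataset import sample_patches
from .augment import AugmentConfig, augment_patch
from .metrics import evaluate_semantic
from .nn import (
    Adam,
    BilinearUp2,
    Conv1x1,
    Conv2d,
    GroupNorm,
    MaxPool2,
    ReLU,
    softmax,
    weighted_cross_entropy,
)
from .weights import WeightMapParams, compute_weight_map

__all__ = ["TrainConfig", "UNet", "train", "select_model", "predict", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 120
    iters_per_epoch: int = 150
    batch_size: int = 1
    patch_px: int = 400
    initial_lr: float = 1e-3
    lr_decay_factor: float = 0.1  # applied once, at 2/3 of the epochs
    depth: int = 4
    base_channels: int = 64
    groups: int = 8
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    weight_params: WeightMapParams = field(default_factory=WeightMapParams)

    def __post_init__(self) -> None:
        if min(self.epochs, self.iters_per_epoch, self.batch_size, self.patch_px) < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def smoke(cls, seed: int = 0) -> "TrainConfig":
        """Reduced preset: trains on one CPU in minutes."""
        return cls(
            epochs=3,
            iters_per_epoch=20,
            patch_px=128,
            depth=2,
            base_channels=8,
            groups=4,
            seed=seed,
        )


class _ConvBlock:
    def __init__(self, c_in: int, c_out: int, groups: int, rng: np.random.Generator):
        self.layers = [
            Conv2d(c_in, c_out, rng),
            GroupNorm(c_out, groups),
            ReLU(),
            Conv2d(c_out, c_out, rng),
            GroupNorm(c_out, groups),
            ReLU(),
        ]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet:
    """Three-class U-shaped network over (N, 3, H, W) float32 inputs."""

    N_CLASSES = 3

    def __init__(self, depth: int = 4, base_channels: int = 64, groups: int = 8, seed: int = 0):
        self.depth = depth
        self.base_channels = base_channels
        self.groups = groups
        rng = np.random.default_rng(seed)
        ch = base_channels
        self.enc: list[_ConvBlock] = []
        self.pools = [MaxPool2() for _ in range(depth)]
        c_in = 3
        chans = []
        for d in range(depth):
            self.enc.append(_ConvBlock(c_in, ch, groups, rng))
            chans.append(ch)
            c_in, ch = ch, ch * 2
        self.bottleneck = _ConvBlock(c_in, ch, groups, rng)
        self.ups = [BilinearUp2() for _ in range(depth)]
        self.dec: list[_ConvBlock] = []
        for d in reversed(range(depth)):
            skip = chans[d]
            self.dec.append(_ConvBlock(ch + skip, skip, groups, rng))
            ch = skip
        self.head = Conv1x1(ch, self.N_CLASSES, rng)

    # -- plumbing ---------------------------------------------------------
    def _blocks(self):
        yield from self.enc
        yield self.bottleneck
        yield from self.dec

    def parameters(self) -> list[np.ndarray]:
        ps = []
        for blk in self._blocks():
            for l in blk.layers:
                ps.extend(p for _, p in l.params)
        ps.extend(p for _, p in self.head.params)
        return ps

    def gradients(self) -> list[np.ndarray]:
        gs = []
        for blk in self._blocks():
            for l in blk.layers:
                gs.extend(l.grads())
        gs.extend(self.head.grads())
        return gs

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("input must be (N, 3, H, W)")
        if x.shape[2] % (1 << self.depth) or x.shape[3] % (1 << self.depth):
            raise ValueError(f"spatial size must be divisible by {1 << self.depth}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskips = []
        for up, blk, cs in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            d = blk.backward(dy)
            dskips.append(d[:, :cs])
            dy = up.backward(d[:, cs:])
        dy = self.bottleneck.backward(dy)
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy)
            dy = blk.backward(dy + dskip)

    # -- persistence ------------------------------------------------------
    def save(self, path: Path | str) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(
            path,
            depth=self.depth,
            base_channels=self.base_channels,
            groups=self.groups,
            **arrays,
        )

    @classmethod
    def load(cls, path: Path | str) -> "UNet":
        with np.load(path) as z:
            model = cls(
                depth=int(z["depth"]),
                base_channels=int(z["base_channels"]),
                groups=int(z["groups"]),
            )
            for i, p in enumerate(model.parameters()):
                p[...] = z[f"p{i}"]
        return model


def load_checkpoint(path: Path | str) -> UNet:
    return UNet.load(path)


def standardize(rgb: np.ndarray) -> np.ndarray:
    """Per-image channelwise standardization to zero mean, unit variance."""
    x = rgb.astype(np.float32)
    mu = x.mean(axis=(0, 1), keepdims=True)
    sd = x.std(axis=(0, 1), keepdims=True)
    return (x - mu) / np.maximum(sd, 1e-6)


def train(
    samples,
    cfg: TrainConfig,
    outdir: Path | str,
    val_patches: list[tuple[np.ndarray, np.ndarray]] | None = None,
):
    """Train on a sample list (or manifest); one checkpoint per epoch.

    Returns (checkpoint paths, metrics rows).  ``val_patches`` are
    (rgb, semantic) pairs scored with the fiber-class F1 after each epoch.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = UNet(cfg.depth, cfg.base_channels, cfg.groups, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    decay_epoch = max(1, (2 * cfg.epochs) // 3)

    patches = sample_patches(samples, cfg.patch_px, cfg.epochs * cfg.iters_per_epoch, cfg.seed + 1)
    rng = np.random.default_rng(cfg.seed + 2)

    ckpts: list[Path] = []
    log_rows: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        if epoch == decay_epoch + 1:
            opt.lr = cfg.initial_lr * cfg.lr_decay_factor
        losses = []
        for _ in range(cfg.iters_per_epoch):
            rgb, sem, inst = next(patches)
            w = compute_weight_map(inst, sem, cfg.weight_params)
            rgb, sem, inst, w = augment_patch(
                rgb, sem, inst, w, int(rng.integers(1 << 31)), cfg.augment
            )
            x = standardize(rgb).transpose(2, 0, 1)[None]
            logits = model.forward(x)
            loss, dlogits = weighted_cross_entropy(
                logits, sem.astype(np.intp)[None], w[None].astype(np.float32)
            )
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
        row = {"epoch": epoch, "loss": float(np.mean(losses)), "lr": opt.lr}
        if val_patches:
            f1s = [
                evaluate_semantic(predict(model, vr), vs)["f1"] for vr, vs in val_patches
            ]
            row["val_f1"] = float(np.mean(f1s))
        ckpt = outdir / f"ckpt_epoch{epoch:03d}.npz"
        model.save(ckpt)
        ckpts.append(ckpt)
        log_rows.append(row)
    with open(outdir / "metrics.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(log_rows[-1].keys()))
        writer.writeheader()
        writer.writerows(log_rows)
    return ckpts, log_rows


def select_model(
    checkpoints: list[Path | str],
    val_patches: list[tuple[np.ndarray, np.ndarray]],
):
    """Best checkpoint by mean fiber-class F1 on validation patches.

    Ties break toward the later epoch.  Validation patches default to
    held-out synthetic data in this package.
    """
    if not checkpoints or not val_patches:
        raise ValueError("need at least one checkpoint and one validation patch")
    best_path, best_f1 = None, -1.0
    for path in checkpoints:
        model = UNet.load(path)
        f1 = float(
            np.mean([evaluate_semantic(predict(model, vr), vs)["f1"] for vr, vs in val_patches])
        )
        if f1 >= best_f1:
            best_path, best_f1 = path, f1
    return best_path, best_f1


def _pad_to_multiple(x: np.ndarray, mult: int):
    h, w = x.shape[:2]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return x, h, w


def predict(
    model: UNet | Path | str,
    rgb: np.ndarray,
    tile: int = 400,
    overlap: int = 100,
) -> np.ndarray:
    """Class probabilities (H, W, 3) via overlap-tiled inference.

    Images up to the tile size run in one pass; larger images are processed
    in overlapping tiles whose borders are down-weighted so stitching seams
    are suppressed (central-crop style blending).
    """
    if not isinstance(model, UNet):
        model = UNet.load(model)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("input must be an (H, W, 3) RGB image")
    mult = 1 << model.depth
    h, w = rgb.shape[:2]
    # per-image standardization happens once, before tiling, so tiled and
    # whole-image inference see identical inputs
    norm = standardize(rgb)

    def _run(img: np.ndarray) -> np.ndarray:
        x = img.transpose(2, 0, 1)[None]
        logits = model.forward(x)
        return softmax(logits, axis=1)[0].transpose(1, 2, 0)

    if max(h, w) <= tile:
        padded, h0, w0 = _pad_to_multiple(norm, mult)
        return _run(padded)[:h0, :w0]

    tile -= tile % mult
    stride = tile - overlap
    acc = np.zeros((h, w, 3), dtype=np.float64)
    wacc = np.zeros((h, w, 1), dtype=np.float64)
    ramp = np.minimum(np.arange(1, tile + 1), overlap // 2 + 1).astype(np.float64)
    taper = np.minimum(ramp, ramp[::-1])
    tw = (taper[:, None] * taper[None, :])[..., None]
    for r0 in range(0, max(h - overlap, 1), stride):
        for c0 in range(0, max(w - overlap, 1), stride):
            r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
            r0a, c0a = max(0, r1 - tile), max(0, c1 - tile)
            block = norm[r0a:r1, c0a:c1]
            block, bh, bw = _pad_to_multiple(block, mult)
            probs = _run(block)[:bh, :bw]
            acc[r0a:r1, c0a:c1] += probs * tw[:bh, :bw]
            wacc[r0a:r1, c0a:c1] += tw[:bh, :bw]
    return (acc / wacc).astype(np.float32)
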