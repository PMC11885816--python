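"""Seedable procedural-noise primitives.

Every texture in the tissue simulator is built from two primitives:

* **Worley (cellular) noise** — distances to a jittered lattice of feature
  points.  ``f1``/``f2`` are the distances to the nearest and second-nearest
  feature point; the identity of the nearest point (``owner``) partitions the
  plane into cells that read as muscle fibers in cross-section, and the thin
  set where ``f2 - f1`` is small reads as the connective-tissue border
  between neighboring fibers.
* **Fractal value noise (fBm)** — smooth multi-octave scalar fields used for
  stain texture and for domain warping.

All functions are pure in ``(inputs, seed)``: feature points and lattice
values are derived lazily from an integer hash of ``(cell index, seed)``, so
fields are unbounded, seekable and bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseConfig",
    "WorleySample",
    "worley_sample",
    "worley_field",
    "fbm_noise",
    "domain_warp",
]

# SplitMix64 constants; arithmetic is modular uint64 on purpose.
_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Finalizer of the SplitMix64 generator; maps uint64 -> well-mixed uint64."""
    with np.errstate(over="ignore"):
        x = (x + _GAMMA).astype(np.uint64)
        x ^= x >> np.uint64(30)
        x = x * _M1
        x ^= x >> np.uint64(27)
        x = x * _M2
        x ^= x >> np.uint64(31)
    return x


def _hash_cells(ci: np.ndarray, cj: np.ndarray, seed: int, stream: int = 0) -> np.ndarray:
    """Deterministic uint64 hash of integer lattice cell (ci, cj)."""
    with np.errstate(over="ignore"):
        s = np.uint64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF) ^ (np.uint64(stream) * _M2))
        h = _splitmix64(np.asarray(ci, dtype=np.int64).view(np.uint64) * _M1 ^ s)
        h = _splitmix64(h ^ np.asarray(cj, dtype=np.int64).view(np.uint64) * _M2)
    return h


def _hash_to_unit(h: np.ndarray) -> np.ndarray:
    """uint64 -> float64 in [0, 1)."""
    return (h >> np.uint64(11)).astype(np.float64) * (1.0 / (1 << 53))


@dataclass(frozen=True)
class NoiseConfig:
    """Parameters of a cellular-noise field.

    Attributes
    ----------
    feature_density:
        Expected feature points per unit area (points/px²).  One point is
        placed per lattice cell of side ``1/sqrt(feature_density)``.
    jitter:
        Fraction in [0, 1] displacing each point from its cell center; 0
        gives a perfect square lattice, 1 lets points roam the whole cell.
    metric:
        Distance metric; only ``"euclidean"`` is supported.
    seed:
        64-bit integer seed.
    """

    feature_density: float
    jitter: float = 1.0
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.feature_density > 0):
            raise ValueError("feature_density must be > 0")
        if not (0.0 <= self.jitter <= 1.0):
            raise ValueError("jitter must lie in [0, 1]")
        if self.metric != "euclidean":
            raise ValueError(f"unsupported metric: {self.metric!r}")

    @property
    def cell_size(self) -> float:
        return 1.0 / float(np.sqrt(self.feature_density))


@dataclass(frozen=True)
class WorleySample:
    """Distances to the two nearest feature points and the nearest point's id."""

    f1: float
    f2: float
    owner_id: int


def _feature_points(ci: np.ndarray, cj: np.ndarray, cfg: NoiseConfig):
    """Feature point (row, col) and id for each integer lattice cell.

    The point sits at the cell center displaced by ``jitter`` times a
    hash-derived uniform offset in (-1/2, 1/2) per axis, so it never leaves
    its cell.  Ids are the (non-negative) hashes themselves: stable under any
    query-window translation.
    """
    h = _hash_cells(ci, cj, cfg.seed)
    u = _hash_to_unit(h)
    v = _hash_to_unit(_splitmix64(h))
    s = cfg.cell_size
    pr = (ci + 0.5 + cfg.jitter * (u - 0.5)) * s
    pc = (cj + 0.5 + cfg.jitter * (v - 0.5)) * s
    ids = (h >> np.uint64(1)).astype(np.int64)  # non-negative
    return pr, pc, ids


# 5x5 cell neighborhood: provably sufficient for exact f1/f2 at any jitter,
# where a 3x3 scan can miss the true second-nearest in worst-case layouts.
_NEIGH = np.array([(di, dj) for di in range(-2, 3) for dj in range(-2, 3)])


def worley_sample(point, cfg: NoiseConfig) -> WorleySample:
    """Exact cellular-noise sample at one (row, col) coordinate in px."""
    p = np.asarray(point, dtype=np.float64)
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise ValueError("point must be a finite (row, col) pair")
    f1, f2, owner = worley_field_at(p[0:1], p[1:2], cfg)
    return WorleySample(float(f1[0]), float(f2[0]), int(owner[0]))


def worley_field_at(rows: np.ndarray, cols: np.ndarray, cfg: NoiseConfig):
    """Vectorized Worley evaluation at arbitrary (possibly warped) coordinates.

    Returns (f1, f2, owner) arrays of the broadcast shape of rows/cols.
    """
    r = np.asarray(rows, dtype=np.float64)
    c = np.asarray(cols, dtype=np.float64)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(c))):
        raise ValueError("coordinates must be finite")
    shape = np.broadcast(r, c).shape
    r = np.broadcast_to(r, shape).ravel()
    c = np.broadcast_to(c, shape).ravel()
    s = cfg.cell_size
    base_i = np.floor(r / s).astype(np.int64)
    base_j = np.floor(c / s).astype(np.int64)

    # hash once per unique lattice cell in range, then gather per pixel:
    # orders of magnitude cheaper than hashing per (pixel, neighbor)
    ilo, ihi = int(base_i.min()) - 2, int(base_i.max()) + 2
    jlo, jhi = int(base_j.min()) - 2, int(base_j.max()) + 2
    gi, gj = np.meshgrid(
        np.arange(ilo, ihi + 1, dtype=np.int64),
        np.arange(jlo, jhi + 1, dtype=np.int64),
        indexing="ij",
    )
    grid_pr, grid_pc, grid_ids = _feature_points(gi, gj, cfg)

    bi = base_i - ilo
    bj = base_j - jlo
    f1 = np.full(r.shape, np.inf)
    f2 = np.full(r.shape, np.inf)
    owner = np.zeros(r.shape, dtype=np.int64)
    for di, dj in _NEIGH:
        ii = bi + di
        jj = bj + dj
        d = np.hypot(grid_pr[ii, jj] - r, grid_pc[ii, jj] - c)
        closer = d < f1
        np.minimum(f2, d, out=f2)
        f2[closer] = f1[closer]  # old nearest becomes second-nearest
        owner[closer] = grid_ids[ii, jj][closer]
        f1[closer] = d[closer]
    return f1.reshape(shape), f2.reshape(shape), owner.reshape(shape)


def worley_field(shape, cfg: NoiseConfig):
    """Worley f1/f2/owner maps sampled at pixel centers of an image grid.

    Element ``[r, c]`` equals ``worley_sample((r, c), cfg)``.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 1 or cols < 1:
        raise ValueError("shape must be at least 1x1")
    rr, cc = np.meshgrid(
        np.arange(rows, dtype=np.float64),
        np.arange(cols, dtype=np.float64),
        indexing="ij",
    )
    return worley_field_at(rr, cc, cfg)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    return t * t * (3.0 - 2.0 * t)


def _value_noise(rr: np.ndarray, cc: np.ndarray, wavelength: float, seed: int) -> np.ndarray:
    """Single-octave value noise in [0, 1]: smoothstep-interpolated lattice hashes."""
    gr = rr / wavelength
    gc = cc / wavelength
    i0 = np.floor(gr).astype(np.int64)
    j0 = np.floor(gc).astype(np.int64)
    tr = _smoothstep(gr - i0)
    tc = _smoothstep(gc - j0)
    ilo, jlo = int(i0.min()), int(j0.min())
    gi, gj = np.meshgrid(
        np.arange(ilo, int(i0.max()) + 2, dtype=np.int64),
        np.arange(jlo, int(j0.max()) + 2, dtype=np.int64),
        indexing="ij",
    )
    vals = _hash_to_unit(_hash_cells(gi, gj, seed, stream=7))
    bi, bj = i0 - ilo, j0 - jlo
    v00 = vals[bi, bj]
    v01 = vals[bi, bj + 1]
    v10 = vals[bi + 1, bj]
    v11 = vals[bi + 1, bj + 1]
    top = v00 + (v01 - v00) * tc
    bot = v10 + (v11 - v10) * tc
    return top + (bot - top) * tr


def fbm_noise(
    shape,
    octaves: int,
    base_wavelength: float,
    persistence: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Fractal (multi-octave) value noise in [0, 1].

    Octave ``k`` contributes value noise at wavelength ``base_wavelength/2^k``
    with amplitude ``persistence^k``; the sum is normalized by the total
    amplitude, so the bounds [0, 1] are exact and the mean is ~0.5.
    """
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    if not (base_wavelength > 0):
        raise ValueError("base_wavelength must be > 0")
    if not (0 < persistence <= 1):
        raise ValueError("persistence must lie in (0, 1]")
    rows, cols = int(shape[0]), int(shape[1])
    rr, cc = np.meshgrid(
        np.arange(rows, dtype=np.float64),
        np.arange(cols, dtype=np.float64),
        indexing="ij",
    )
    return fbm_at(rr, cc, octaves, base_wavelength, persistence, seed)


def fbm_at(
    rr: np.ndarray,
    cc: np.ndarray,
    octaves: int,
    base_wavelength: float,
    persistence: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """fBm evaluated at arbitrary coordinates (see :func:`fbm_noise`)."""
    out = np.zeros(np.broadcast(rr, cc).shape, dtype=np.float64)
    amp = 1.0
    total = 0.0
    wl = float(base_wavelength)
    for k in range(octaves):
        out += amp * _value_noise(np.asarray(rr, float), np.asarray(cc, float), wl, seed + 101 * k)
        total += amp
        amp *= persistence
        wl *= 0.5
    return out / total


def domain_warp(
    coords,
    amplitude: float,
    warp_seed: int,
    warp_wavelength: float,
    octaves: int = 3,
):
    """Displace a (rows, cols) coordinate grid by a smooth vector field.

    Each axis is displaced by ``amplitude * (2*fbm - 1)`` with an independent
    fBm stream, so per-axis |displacement| <= amplitude and ``amplitude = 0``
    is the identity.  Warping the query coordinates of a Worley field turns
    its polygonal cells into organic, fiber-like outlines.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rr, cc = coords
    rr = np.asarray(rr, dtype=np.float64)
    cc = np.asarray(cc, dtype=np.float64)
    if amplitude == 0:
        return rr.copy(), cc.copy()
    dr = 2.0 * fbm_at(rr, cc, octaves, warp_wavelength, seed=warp_seed) - 1.0
    dc = 2.0 * fbm_at(rr, cc, octaves, warp_wavelength, seed=warp_seed + 7919) - 1.0
    return rr + amplitude * dr, cc + amplitude * dc
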