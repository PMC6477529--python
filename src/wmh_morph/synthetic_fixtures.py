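"""Synthetic lesion fixtures with known ground truth.

Real FLAIR data behind the method are not redistributable, so every other
module is exercised against volumes generated here: bright lesions of
controllable shape family (disc, ellipse, cross, random blob), size,
boundary edge steepness, and interior texture, on a darker noisy
background.

The canonical intensity model is piecewise linear in the distance to the
lesion boundary: plateau in the deep core, descent to a fraction
``boundary_level`` of the dynamic range at the mask edge (a
probability-threshold segmentation cuts through the middle of the true
intensity ramp), then a penumbral ramp of ``edge_width`` voxels outside
the boundary down to background.  A linear ramp keeps every voxel's
noise-free value in closed form, which the oracle tests rely on.  All
randomness flows from one explicit seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .lesion_io import save_volume

__all__ = [
    "FixtureSpec",
    "make_shape",
    "make_intensity",
    "ramp_profile",
    "make_planted_clusters",
    "match_score",
    "DemoVolume",
    "make_demo_volume",
    "write_demo_volume",
]

FAMILIES = ("disc", "ellipse", "cross", "blob")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic lesion."""

    family: str = "disc"
    size: int = 20
    edge_width: int = 3
    plateau: float = 120.0
    background: float = 40.0
    core_depth: int = 4
    boundary_level: float = 0.55
    noise_sd: float = 3.0
    n_slices: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown shape family {self.family!r}")
        if self.plateau <= self.background:
            raise ValueError("plateau must exceed background")
        if self.edge_width < 0:
            raise ValueError("edge width must be >= 0")


def _disc(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    return (rows - c) ** 2 + (cols - c) ** 2 <= (size / 2.0) ** 2


def _ellipse(size: int, rng: np.random.Generator, ratio: float = 0.4) -> np.ndarray:
    c = (size - 1) / 2.0
    a = size / 2.0
    b = max(1.5, ratio * a)
    angle = rng.uniform(0.0, np.pi)
    rows, cols = np.mgrid[0:size, 0:size]
    y = rows - c
    x = cols - c
    u = x * np.cos(angle) + y * np.sin(angle)
    v = -x * np.sin(angle) + y * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _cross(size: int) -> np.ndarray:
    t = max(1, size // 5)
    if (size - t) % 2:  # keep the arms centered so 90-degree symmetry is exact
        t += 1
    t = min(t, size)
    a = (size - t) // 2
    mask = np.zeros((size, size), dtype=bool)
    mask[a : a + t, :] = True
    mask[:, a : a + t] = True
    return mask


def _blob(size: int, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    margin = max(1, size // 8)
    pos = np.array([size // 2, size // 2])
    mask[pos[0], pos[1]] = True
    steps = rng.integers(-1, 2, size=(3 * size, 2))
    for step in steps:
        pos = np.clip(pos + step, margin, size - 1 - margin)
        mask[pos[0], pos[1]] = True
    struct = ndimage.generate_binary_structure(2, 2)
    return ndimage.binary_dilation(mask, structure=struct, iterations=max(1, size // 8))


def make_shape(family: str, size: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """A deterministic 8-connected binary mask of the requested family and size.

    ``size`` is the grid (and approximate bounding square) side.  Discs and
    crosses are fully deterministic; ellipse orientation and blob growth are
    drawn from the seeded generator.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown shape family {family!r}")
    min_size = {"disc": 4, "ellipse": 6, "cross": 5, "blob": 8}[family]
    if size < min_size:
        raise ValueError(f"size {size} too small to render a {family}")
    rng = np.random.default_rng(seed)
    if family == "disc":
        return _disc(size)
    if family == "ellipse":
        return _ellipse(size, rng)
    if family == "cross":
        return _cross(size)
    return _blob(size, rng)


def ramp_profile(
    mask: np.ndarray,
    edge_width: int,
    core_depth: int = 4,
    boundary_level: float = 0.55,
) -> np.ndarray:
    """Noise-free edge profile in [0, 1] around and inside a lesion mask.

    Mimics how a probability-0.5 segmentation cuts through the middle of a
    lesion's intensity ramp: the innermost voxels sit at 1 (plateau), the
    profile descends linearly to ``boundary_level`` at the mask boundary
    (over ``core_depth`` voxels), and continues descending outside the
    boundary from ``boundary_level`` to 0 over ``edge_width + 1`` voxels
    (the penumbral ramp).  With Euclidean distances ``d_in`` (inside, >= 1
    at the boundary) and ``d_out`` (outside, >= 1 in the first ring):

    - inside:  ``beta + (1 - beta) * clip((d_in - 1) / c, 0, 1)``
    - outside: ``beta * clip(1 - d_out / (w + 1), 0, 1)``

    ``edge_width = 0`` gives a step edge: every outside voxel at background.
    """
    m = np.asarray(mask, dtype=bool)
    beta = float(boundary_level)
    if not 0.0 < beta <= 1.0:
        raise ValueError("boundary_level must lie in (0, 1]")
    c = max(1.0, float(core_depth))
    d_in = ndimage.distance_transform_edt(m)
    d_out = ndimage.distance_transform_edt(~m)
    inside = beta + (1.0 - beta) * np.clip((d_in - 1.0) / c, 0.0, 1.0)
    outside = beta * np.clip(1.0 - d_out / (edge_width + 1.0), 0.0, 1.0)
    return np.where(m, inside, outside)


def make_intensity(
    mask: np.ndarray,
    plateau: float = 120.0,
    background: float = 40.0,
    edge_width: int = 3,
    core_depth: int = 4,
    boundary_level: float = 0.55,
    noise_sd: float = 0.0,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic FLAIR-like intensity image for a lesion mask.

    ``background + (plateau - background) * ramp_profile(...)`` plus seeded
    Gaussian noise: plateau-level core, interior descent to
    ``boundary_level`` at the mask edge, and a penumbral ramp of
    ``edge_width`` voxels outside it.  The interior descent gives lesions a
    non-trivial intensity range (gMin < gMax), as real lesions have.
    """
    if plateau <= background:
        raise ValueError("plateau must exceed background")
    profile = ramp_profile(
        mask, edge_width=edge_width, core_depth=core_depth, boundary_level=boundary_level
    )
    img = background + (plateau - background) * profile
    if noise_sd > 0:
        gen = np.random.default_rng(rng)
        img = img + gen.normal(0.0, noise_sd, size=img.shape)
    return img


def make_planted_clusters(
    k: int,
    n_per: int = 50,
    sep: float = 10.0,
    dim: int = 3,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian clusters (unit SD) with pairwise center distance >= ``sep``.

    Returns (features, labels, centers); labels identify the planted
    cluster of each row for recovery scoring.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    span = 4.0 * sep * max(1.0, k / 4.0)
    for _ in range(10_000):
        centers = rng.uniform(0.0, span, size=(k, dim))
        if k == 1:
            break
        diffs = centers[:, None, :] - centers[None, :, :]
        dists = np.sqrt((diffs**2).sum(axis=-1))
        if dists[np.triu_indices(k, 1)].min() >= sep:
            break
    else:  # pragma: no cover - rejection sampling virtually always succeeds
        raise RuntimeError("could not place cluster centers")
    labels = np.repeat(np.arange(k), n_per)
    x = centers[labels] + rng.normal(0.0, 1.0, size=(k * n_per, dim))
    return x, labels, centers


def match_score(labels_true, labels_pred) -> float:
    """Best-permutation label agreement between two clusterings, in [0, 1]."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape:
        raise ValueError("label arrays must be aligned")
    t_vals = np.unique(t)
    p_vals = np.unique(p)
    confusion = np.zeros((t_vals.size, p_vals.size), dtype=np.int64)
    for i, tv in enumerate(t_vals):
        for j, pv in enumerate(p_vals):
            confusion[i, j] = int(((t == tv) & (p == pv)).sum())
    rows, cols = linear_sum_assignment(-confusion)
    return float(confusion[rows, cols].sum()) / t.size


@dataclass
class DemoVolume:
    """A multi-slice synthetic study: volume, probability map, mask, manifest."""

    volume: np.ndarray
    probability_map: np.ndarray
    mask: np.ndarray
    manifest: pd.DataFrame
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)


def make_demo_volume(
    seed: int = 0,
    families: tuple[str, ...] = ("disc", "ellipse", "cross"),
    n_per_family: int = 6,
    grid: tuple[int, int, int] = (200, 200, 9),
    size_range: tuple[int, int] = (16, 34),
    edge_width_range: tuple[int, int] = (2, 6),
    core_depth_range: tuple[int, int] = (3, 6),
    boundary_level_range: tuple[float, float] = (0.45, 0.65),
    plateau: float = 120.0,
    background: float = 40.0,
    noise_sd: float = 3.0,
    slices_per_lesion: int = 3,
) -> DemoVolume:
    """A synthetic multi-lesion study volume with ground-truth manifest.

    Lesions are placed on a non-overlapping cell grid, each spanning
    ``slices_per_lesion`` consecutive slices (so 2D components link into 3D
    lesions), with family-specific masks and per-lesion penumbral ramp
    parameters drawn from the given ranges (so lesions differ in texture
    and edge steepness).  The probability map is > 0.5 exactly on lesion
    voxels and < 0.5 elsewhere, so thresholding recovers the ground-truth
    mask.
    """
    rng = np.random.default_rng(seed)
    nr, nc, nz = grid
    cell = size_range[1] + 2 * (edge_width_range[1] + 6)
    cols = nc // cell
    rows = nr // cell
    band = slices_per_lesion + 1
    bands = max(0, (nz - 1) // band)
    capacity = rows * cols * bands
    lesion_specs = [(fam, i) for fam in families for i in range(n_per_family)]
    if len(lesion_specs) > capacity:
        raise ValueError(
            f"{len(lesion_specs)} lesions do not fit: capacity {capacity} "
            f"(grid {grid}, cell {cell})"
        )
    order = rng.permutation(len(lesion_specs))

    mask3d = np.zeros(grid, dtype=bool)
    records = []
    slots = [(b, r, c) for b in range(bands) for r in range(rows) for c in range(cols)]
    profile3d = np.zeros(grid, dtype=np.float64)
    for slot, idx in zip(slots, order):
        family, _ = lesion_specs[idx]
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        shape = make_shape(family, size, seed=rng)
        edge_width = int(rng.integers(edge_width_range[0], edge_width_range[1] + 1))
        core_depth = int(rng.integers(core_depth_range[0], core_depth_range[1] + 1))
        boundary_level = float(rng.uniform(*boundary_level_range))
        b, r, c = slot
        r0 = r * cell + (cell - size) // 2
        c0 = c * cell + (cell - size) // 2
        z0 = 1 + b * band
        z1 = z0 + slices_per_lesion - 1
        pad = edge_width + 2
        patch_mask = np.pad(shape, pad)
        patch_profile = ramp_profile(
            patch_mask, edge_width=edge_width, core_depth=core_depth,
            boundary_level=boundary_level,
        )
        rs = slice(r0 - pad, r0 + size + pad)
        cs = slice(c0 - pad, c0 + size + pad)
        for z in range(z0, z1 + 1):
            mask3d[r0 : r0 + size, c0 : c0 + size, z] |= shape
            profile3d[rs, cs, z] = np.maximum(profile3d[rs, cs, z], patch_profile)
        records.append(
            {
                "family": family,
                "size": size,
                "row": r0,
                "col": c0,
                "slice_first": z0,
                "slice_last": z1,
                "n_voxels_2d": int(shape.sum()),
                "edge_width": edge_width,
                "core_depth": core_depth,
                "boundary_level": boundary_level,
            }
        )

    volume = background + (plateau - background) * profile3d
    if noise_sd > 0:
        volume += rng.normal(0.0, noise_sd, size=grid)

    pmap = rng.uniform(0.0, 0.3, size=grid)
    pmap[mask3d] = rng.uniform(0.55, 0.95, size=int(mask3d.sum()))

    manifest = pd.DataFrame(records).sort_values(
        ["slice_first", "row", "col"], ignore_index=True
    )
    return DemoVolume(volume=volume, probability_map=pmap, mask=mask3d, manifest=manifest)


def write_demo_volume(demo: DemoVolume, out_dir: str | Path) -> dict[str, Path]:
    """Write a demo study as NIfTI volumes plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / "volume.nii.gz",
        "probability_map": out / "probability_map.nii.gz",
        "mask": out / "mask.nii.gz",
        "manifest": out / "manifest.csv",
    }
    save_volume(demo.volume, paths["volume"], demo.voxel_size)
    save_volume(demo.probability_map, paths["probability_map"], demo.voxel_size)
    save_volume(demo.mask.astype(np.uint8), paths["mask"], demo.voxel_size)
    demo.manifest.to_csv(paths["manifest"], index=False)
    return paths
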