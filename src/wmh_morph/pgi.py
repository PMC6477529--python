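"""Potential growth index (PGI): region growing at lesion boundaries.

Tissue immediately around a bright lesion that shares the lesion's signal
intensity (the penumbra) is at risk of converting to lesion.  Starting
from the lesion's boundary voxels, a seed-based region-growing pass over
8-neighborhoods collects non-lesion voxels whose intensity ``f(p)``
satisfies ``gMax - f(p) < gamma * (gMax - gMin)``, where gMax/gMin are the
despiked extremes of the parent 3D-linked lesion and gamma (default 1.02)
controls how steep an edge still counts as growth-permissive.

The growth voxels are then located within ``l`` one-voxel-thick
4-connected rings around the mask (default 3).  With ring weights
``w_i = i / (l(l+1)/2)`` (outer rings weigh more) and ring sizes
``|E_i|``, the index is ``P_g = sum_i GV_i * w_i / V_l`` where ``GV_i``
is the growth-voxel count in ring i and ``V_l`` the total ring size.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GrowthRegion",
    "LayerSet",
    "PGIResult",
    "AnovaResult",
    "boundary_seeds",
    "region_grow",
    "generate_layers",
    "layer_weights",
    "compute_pgi",
    "pgi_for_lesion",
    "anova_pgi_by_cluster",
]

DEFAULT_GAMMA = 1.02
DEFAULT_LAYERS = 3

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_OFFSETS_8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


@dataclass(frozen=True)
class GrowthRegion:
    """Growth-voxel set R_g (boolean grid) found around one lesion."""

    region: np.ndarray
    gamma: float

    @property
    def n_voxels(self) -> int:
        return int(self.region.sum())


@dataclass(frozen=True)
class LayerSet:
    """``l`` disjoint one-voxel-thick 4-connected rings around a mask."""

    layers: list[np.ndarray]

    @property
    def sizes(self) -> list[int]:
        return [int(e.sum()) for e in self.layers]

    @property
    def total(self) -> int:
        return int(sum(self.sizes))


@dataclass(frozen=True)
class PGIResult:
    """Per-layer growth-voxel counts, layer weights, and the scalar index."""

    growth_per_layer: np.ndarray
    layer_sizes: np.ndarray
    weights: np.ndarray
    p_g: float


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    table: pd.DataFrame


def boundary_seeds(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one non-mask 4-neighbor, as (row, col) pairs.

    Neighbors outside the image count as non-mask, so voxels on the image
    edge are boundary voxels.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("boundary of an empty mask is undefined")
    interior = ndimage.binary_erosion(m, structure=_STRUCT_4, border_value=0)
    return np.argwhere(m & ~interior)


def region_grow(
    mask: np.ndarray,
    intensity_slice: np.ndarray,
    gmax: float,
    gmin: float,
    gamma: float = DEFAULT_GAMMA,
    forbidden: np.ndarray | None = None,
    max_rings: int | None = None,
) -> GrowthRegion:
    """Breadth-first growth of the penumbral voxel set from the mask boundary.

    A non-mask, unvisited voxel p in the 8-neighborhood of a seed joins the
    growth set iff ``gMax - f(p) < gamma * (gMax - gMin)`` (strict; ties are
    rejected); accepted voxels seed further growth.  Voxels of other lesions
    (``forbidden``) are never growth voxels.  ``max_rings`` optionally stops
    expansion beyond that 4-connected ring distance from the mask (a speed
    cap; growth within the rings can differ slightly from the uncapped run
    when a path re-enters from outside the cap).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gmax < gmin:
        raise ValueError("gMax must be >= gMin")
    m = np.asarray(mask, dtype=bool)
    f = np.asarray(intensity_slice, dtype=np.float64)
    if m.shape != f.shape:
        raise ValueError("mask and intensity slice must share a grid")
    blocked = m.copy()
    if forbidden is not None:
        blocked |= np.asarray(forbidden, dtype=bool)
    allowed = None
    if max_rings is not None:
        allowed = ndimage.binary_dilation(m, structure=_STRUCT_4, iterations=max_rings)
    threshold = gamma * (gmax - gmin)
    nrows, ncols = m.shape
    region = np.zeros_like(m)
    visited = blocked.copy()
    queue = deque(map(tuple, boundary_seeds(m)))
    while queue:
        r, c = queue.popleft()
        for dr, dc in _OFFSETS_8:
            pr, pc = r + dr, c + dc
            if not (0 <= pr < nrows and 0 <= pc < ncols):
                continue
            if visited[pr, pc]:
                continue
            visited[pr, pc] = True
            if allowed is not None and not allowed[pr, pc]:
                continue
            if gmax - f[pr, pc] < threshold:
                region[pr, pc] = True
                queue.append((pr, pc))
    return GrowthRegion(region=region, gamma=float(gamma))


def generate_layers(mask: np.ndarray, n_layers: int = DEFAULT_LAYERS) -> LayerSet:
    """Successive one-voxel-thick 4-connected rings around the mask.

    Ring i is the 4-dilation front at distance i, excluding the mask and
    all previous rings; rings are clipped at the image bounds.
    """
    if n_layers < 1:
        raise ValueError("layer count must be >= 1")
    covered = np.asarray(mask, dtype=bool).copy()
    layers = []
    for _ in range(n_layers):
        ring = ndimage.binary_dilation(covered, structure=_STRUCT_4) & ~covered
        layers.append(ring)
        covered |= ring
    return LayerSet(layers=layers)


def layer_weights(n_layers: int) -> np.ndarray:
    """Increasing layer weights ``w_i = i / sum_{j=1}^{l} j``; they sum to 1."""
    if n_layers < 1:
        raise ValueError("layer count must be >= 1")
    i = np.arange(1, n_layers + 1, dtype=np.float64)
    return i / i.sum()


def compute_pgi(region: GrowthRegion, layers: LayerSet) -> PGIResult:
    """Layer-weighted potential growth index from a growth region and rings.

    ``GV_i = |R_g intersect E_i|``; growth voxels beyond the outermost ring
    are ignored.  ``P_g = sum_i GV_i w_i / V_l`` with ``V_l`` the total ring
    voxel count; always in [0, 1].
    """
    sizes = np.array(layers.sizes, dtype=np.float64)
    total = sizes.sum()
    if total == 0:
        raise ValueError("layer set is empty (mask fills the image)")
    gv = np.array([int((region.region & e).sum()) for e in layers.layers], dtype=np.float64)
    w = layer_weights(len(layers.layers))
    p_g = float((gv * w).sum() / total)
    return PGIResult(growth_per_layer=gv, layer_sizes=sizes, weights=w, p_g=p_g)


def pgi_for_lesion(
    mask: np.ndarray,
    intensity_slice: np.ndarray,
    gmax: float,
    gmin: float,
    gamma: float = DEFAULT_GAMMA,
    n_layers: int = DEFAULT_LAYERS,
    forbidden: np.ndarray | None = None,
) -> PGIResult:
    """Convenience: region growing + ring construction + PGI for one lesion image."""
    grown = region_grow(mask, intensity_slice, gmax, gmin, gamma=gamma, forbidden=forbidden)
    layers = generate_layers(mask, n_layers=n_layers)
    return compute_pgi(grown, layers)


def anova_pgi_by_cluster(pgi_values, cluster_labels, min_group: int = 2) -> AnovaResult:
    """One-way ANOVA of PGI across clusters, with a per-cluster summary table.

    Requires at least two clusters, each with ``min_group`` or more members.
    A fully degenerate input (zero variance everywhere) returns F = 0, P = 1.
    """
    values = np.asarray(pgi_values, dtype=np.float64)
    labels = np.asarray(cluster_labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("pgi_values and cluster_labels must be aligned")
    groups = []
    rows = []
    for lab in np.unique(labels):
        g = values[labels == lab]
        if g.shape[0] < min_group:
            raise ValueError(f"cluster {lab!r} has fewer than {min_group} members")
        groups.append(g)
        rows.append(
            {
                "cluster": lab,
                "n": int(g.shape[0]),
                "pgi_mean": float(g.mean()),
                "pgi_sd": float(g.std(ddof=1)) if g.shape[0] > 1 else 0.0,
            }
        )
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two clusters")
    table = pd.DataFrame(rows)
    if np.allclose(values, values[0]):
        return AnovaResult(f=0.0, p=1.0, table=table)
    f, p = stats.f_oneway(*groups)
    return AnovaResult(f=float(f), p=float(p), table=table)
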