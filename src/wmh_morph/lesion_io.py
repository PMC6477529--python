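"""Lesion I/O: volumes, probability-map thresholding, 2D components, 3D linking.

Segmentation itself (e.g. the LST/LPA lesion prediction algorithm) is out
of scope; this module starts from an intensity volume plus a co-registered
binary lesion mask or lesion-probability map.  Probability maps are
thresholded (default 0.5, strict ``>``), per-slice connected components
larger than a minimum voxel count (default: more than 10 connected voxels)
become :class:`LesionComponent2D` objects, and components on adjacent
slices that touch directly above/below or diagonally are linked into
:class:`Lesion3D` aggregates whose despiked intensity extremes (gMin,
gMax) anchor texture normalization and region growing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .texture_fuzzy import despike

__all__ = [
    "IntensityVolume",
    "LesionComponent2D",
    "Lesion3D",
    "load_volume",
    "save_volume",
    "threshold_probability_map",
    "extract_lesions_2d",
    "extract_lesions_volume",
    "link_lesions_3d",
    "build_lesions_3d",
    "size_histogram",
    "components_table",
    "lesions3d_table",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_VOXELS = 10

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar MR volume with voxel spacing and a through-plane axis."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_axis: int = 2

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise ValueError("intensity volume must be 3D")
        if min(vox.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel size components must be > 0")
        if not 0 <= self.slice_axis <= 2:
            raise ValueError("slice_axis must be 0, 1 or 2")
        object.__setattr__(self, "voxels", vox)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.slice_axis]

    def get_slice(self, index: int) -> np.ndarray:
        return np.take(self.voxels, index, axis=self.slice_axis)


@dataclass
class LesionComponent2D:
    """One connected lesion region on a single slice.

    ``voxels`` holds 0-based (row, col) in-plane coordinates; the bounding
    square side is the side of the smallest enclosing square (max of the
    bounding-box height and width).
    """

    slice_index: int
    voxels: np.ndarray
    lesion_id: int | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.intp).reshape(-1, 2)
        if vox.shape[0] == 0:
            raise ValueError("a lesion component needs at least one voxel")
        self.voxels = vox

    @property
    def size(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        rmin, cmin = self.voxels.min(axis=0)
        rmax, cmax = self.voxels.max(axis=0)
        return int(rmin), int(cmin), int(rmax), int(cmax)

    @property
    def bounding_square_side(self) -> int:
        rmin, cmin, rmax, cmax = self.bounding_box
        return int(max(rmax - rmin + 1, cmax - cmin + 1))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the component as a boolean mask on a grid of ``shape``."""
        out = np.zeros(shape, dtype=bool)
        out[self.voxels[:, 0], self.voxels[:, 1]] = True
        return out

    def voxel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.voxels}


@dataclass
class Lesion3D:
    """A cross-slice-linked lesion aggregate ("WMH3D").

    ``component_intensities`` holds the despiked intensity values per
    component (aligned with ``components``); ``gmin``/``gmax`` are the
    despiked extremes over the whole aggregate.
    """

    components: list[LesionComponent2D]
    component_intensities: list[np.ndarray]
    gmin: float
    gmax: float
    lesion_id: int | None = None

    @property
    def intensities(self) -> np.ndarray:
        return np.concatenate(self.component_intensities)

    @property
    def n_voxels(self) -> int:
        return sum(c.size for c in self.components)

    @property
    def slice_indices(self) -> list[int]:
        return sorted({c.slice_index for c in self.components})

    @classmethod
    def from_components(
        cls,
        components: list[LesionComponent2D],
        volume: np.ndarray | IntensityVolume,
        slice_axis: int = 2,
        lesion_id: int | None = None,
    ) -> "Lesion3D":
        if isinstance(volume, IntensityVolume):
            slice_axis = volume.slice_axis
            volume = volume.voxels
        raw = []
        for comp in components:
            sl = np.take(volume, comp.slice_index, axis=slice_axis)
            raw.append(np.asarray(sl[comp.voxels[:, 0], comp.voxels[:, 1]], dtype=np.float64))
        clamped = despike(np.concatenate(raw))
        gmin = float(clamped.min())
        gmax = float(clamped.max())
        sizes = np.cumsum([0] + [r.size for r in raw])
        per_comp = [clamped[sizes[i] : sizes[i + 1]] for i in range(len(raw))]
        return cls(
            components=list(components),
            component_intensities=per_comp,
            gmin=gmin,
            gmax=gmax,
            lesion_id=lesion_id,
        )


def load_volume(path: str | Path, slice_axis: int = 2) -> IntensityVolume:
    """Read a NIfTI volume (.nii/.nii.gz) into an :class:`IntensityVolume`."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(voxels=data, voxel_size=zooms, slice_axis=slice_axis)


def save_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    """Write a 3D array as NIfTI with a diagonal affine from the voxel size."""
    affine = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def threshold_probability_map(pmap: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary lesion mask: voxels whose lesion probability strictly exceeds the threshold."""
    values = np.asarray(pmap, dtype=np.float64)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        raise ValueError("probability map values must lie in [0, 1]")
    return values > threshold


def extract_lesions_2d(
    mask_slice: np.ndarray,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    connectivity: int = 8,
    slice_index: int = 0,
) -> list[LesionComponent2D]:
    """Connected components of a 2D mask with strictly more than ``min_voxels`` voxels.

    With the default ``min_voxels=10``, components of 11 or more connected
    voxels are kept as probable lesions.  Connectivity is 8 by default
    (diagonal in-plane neighbors connect), configurable to 4.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask_slice, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask slice must be 2D")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labels, n_labels = ndimage.label(mask, structure=structure)
    out = []
    for lab in range(1, n_labels + 1):
        vox = np.argwhere(labels == lab)
        if vox.shape[0] > min_voxels:
            out.append(LesionComponent2D(slice_index=slice_index, voxels=vox))
    return out


def extract_lesions_volume(
    mask: np.ndarray,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    connectivity: int = 8,
    slice_axis: int = 2,
) -> list[LesionComponent2D]:
    """Per-slice lesion components of a 3D binary mask, ids assigned in order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    components: list[LesionComponent2D] = []
    for z in range(mask.shape[slice_axis]):
        sl = np.take(mask, z, axis=slice_axis)
        components.extend(
            extract_lesions_2d(sl, min_voxels=min_voxels, connectivity=connectivity, slice_index=z)
        )
    for i, comp in enumerate(components):
        comp.lesion_id = i
    return components


def link_lesions_3d(components: list[LesionComponent2D]) -> list[list[LesionComponent2D]]:
    """Partition 2D components into 3D lesions by adjacent-slice contact.

    Two components merge when a voxel of one connects directly (same in-plane
    position) or diagonally (8-neighborhood in-plane) to a voxel of the other
    on an adjacent slice — i.e. 26-connectivity restricted to consecutive
    slices.  Each component lands in exactly one group; isolated components
    become singleton groups, ordered by (first slice, position).
    """
    n = len(components)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    by_voxel: dict[tuple[int, int, int], int] = {}
    for i, comp in enumerate(components):
        for r, c in comp.voxels:
            by_voxel[(comp.slice_index, int(r), int(c))] = i
    for i, comp in enumerate(components):
        z = comp.slice_index
        for r, c in comp.voxels:
            for dz in (-1, 1):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        j = by_voxel.get((z + dz, int(r) + dr, int(c) + dc))
                        if j is not None:
                            union(i, j)

    groups: dict[int, list[LesionComponent2D]] = {}
    for i, comp in enumerate(components):
        groups.setdefault(find(i), []).append(comp)
    ordered = sorted(
        groups.values(),
        key=lambda g: (min(c.slice_index for c in g), tuple(g[0].voxels[0])),
    )
    return ordered


def build_lesions_3d(
    components: list[LesionComponent2D],
    volume: np.ndarray | IntensityVolume,
    slice_axis: int = 2,
) -> list[Lesion3D]:
    """Link components across slices and attach despiked intensities from a volume."""
    groups = link_lesions_3d(components)
    lesions = []
    for i, group in enumerate(groups):
        lesions.append(
            Lesion3D.from_components(group, volume, slice_axis=slice_axis, lesion_id=i)
        )
    return lesions


def size_histogram(components: list[LesionComponent2D], bin_width: int = 10) -> pd.DataFrame:
    """Histogram of bounding-square sides with cumulative percentages.

    Bins are half-open ``(prev, cur]`` of the given width, labeled by their
    upper edge: the bin labeled 50 covers sides from 41 to 50 (sizes
    40x40-exclusive to 50x50-inclusive).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if not components:
        return pd.DataFrame(columns=["bin", "count", "cumulative_pct"])
    sides = np.array([c.bounding_square_side for c in components], dtype=np.int64)
    bins = -(-sides // bin_width) * bin_width  # ceil to multiple of bin_width
    edges = np.arange(bin_width, bins.max() + bin_width, bin_width)
    counts = np.array([(bins == e).sum() for e in edges], dtype=np.int64)
    cum = 100.0 * np.cumsum(counts) / len(components)
    return pd.DataFrame({"bin": edges, "count": counts, "cumulative_pct": cum})


def components_table(components: list[LesionComponent2D], subject_id: str = "") -> pd.DataFrame:
    """One row per 2D component: id, slice, voxel count, bounding square side."""
    rows = [
        {
            "subject_id": subject_id,
            "component_id": c.lesion_id,
            "slice_index": c.slice_index,
            "n_voxels": c.size,
            "bounding_square_side": c.bounding_square_side,
        }
        for c in components
    ]
    return pd.DataFrame(rows)


def lesions3d_table(lesions: list[Lesion3D], subject_id: str = "") -> pd.DataFrame:
    """One row per 3D-linked lesion: id, slice span, voxel count, gMin/gMax."""
    rows = [
        {
            "subject_id": subject_id,
            "lesion3d_id": les.lesion_id,
            "n_components": len(les.components),
            "n_voxels": les.n_voxels,
            "slice_min": min(les.slice_indices),
            "slice_max": max(les.slice_indices),
            "gmin": les.gmin,
            "gmax": les.gmax,
        }
        for les in lesions
    ]
    return pd.DataFrame(rows)
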