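"""Rotation-invariant Zernike shape descriptors for binary lesion masks.

A segmented lesion mask is isotropically rescaled so that its bounding
square fills a canonical ``side x side`` canvas (60 x 60 by default), the
canvas is mapped into the unit disc, and the image is expanded in the
orthogonal Zernike polynomial basis.  The magnitudes ``|Z_nm|`` of the
complex expansion coefficients are invariant to rotations of the lesion,
which makes them suitable shape features for lesions that occur at
arbitrary orientations.

Two disc mappings are supported:

``circumscribed`` (default)
    The whole canvas lies inside the unit disc (corner pixels reach
    radius ~1), so no foreground is discarded.  The basis is not
    orthogonal when restricted to the square, but magnitudes remain
    rotation invariant for content that stays on the canvas.
``inscribed``
    The unit disc is inscribed in the canvas; pixels outside the disc are
    ignored.  This is the classical convention under which the discrete
    basis is orthogonal and a full-disc image has ``Z_00 ~ 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "NormalizedShapeImage",
    "ZernikeMoments",
    "normalize_shape",
    "radial_polynomial",
    "zernike_basis_indices",
    "zernike_moments",
    "num_distinct_magnitudes",
    "shape_feature_vector",
    "feature_names",
    "reconstruct",
]

DEFAULT_SIDE = 60
DEFAULT_MAX_ORDER = 5


@dataclass(frozen=True)
class NormalizedShapeImage:
    """A lesion mask rescaled onto the canonical square canvas."""

    pixels: np.ndarray
    source_lesion_id: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("normalized shape image must be a square 2D grid")
        if not px.any():
            raise ValueError("normalized shape image has no foreground")
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return int(self.pixels.shape[0])


@dataclass(frozen=True)
class ZernikeMoments:
    """Complex Zernike coefficients ``Z_nm`` indexed by (order n, repetition m)."""

    values: dict
    max_order: int
    side: int
    mapping: str

    def __getitem__(self, nm) -> complex:
        return self.values[nm]

    def magnitude(self, n: int, m: int) -> float:
        return abs(self.values[(n, m)])


def _as_tight_square_mask(obj) -> np.ndarray:
    """Crop a mask (or a lesion component) to its centered bounding square."""
    if hasattr(obj, "voxels") and hasattr(obj, "slice_index"):
        vox = np.asarray(obj.voxels, dtype=int)
        if vox.size == 0:
            raise ValueError("empty lesion")
        rmin, cmin = vox.min(axis=0)
        h, w = vox.max(axis=0) - (rmin, cmin) + 1
        side = int(max(h, w))
        mask = np.zeros((side, side), dtype=bool)
        r_off = (side - h) // 2
        c_off = (side - w) // 2
        mask[vox[:, 0] - rmin + r_off, vox[:, 1] - cmin + c_off] = True
        return mask
    mask = np.asarray(obj, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("expected a 2D mask")
    if not mask.any():
        raise ValueError("empty lesion")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    tight = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    h, w = tight.shape
    side = max(h, w)
    out = np.zeros((side, side), dtype=bool)
    r_off = (side - h) // 2
    c_off = (side - w) // 2
    out[r_off : r_off + h, c_off : c_off + w] = tight
    return out


def normalize_shape(lesion, side: int = DEFAULT_SIDE) -> NormalizedShapeImage:
    """Rescale a lesion mask so its bounding square fills a ``side x side`` canvas.

    The scaling is isotropic (shape-preserving); the foreground centroid is
    translated to the canvas center.  The continuous-valued resampled mask is
    re-binarized at 0.5, preserving its binary nature.

    Parameters
    ----------
    lesion
        A 2D boolean mask, or any object with ``voxels`` ((row, col) pairs)
        and ``slice_index`` attributes.
    side
        Canvas side in pixels; must be >= 8.
    """
    if side < 8:
        raise ValueError("canvas side must be >= 8")
    mask = _as_tight_square_mask(lesion)
    src_side = mask.shape[0]
    centroid = np.argwhere(mask).mean(axis=0)
    scale = side / src_side
    half = (side - 1) / 2.0
    out_r, out_c = np.mgrid[0:side, 0:side]
    # pad with a zero ring so interpolation across the source border stays
    # in-bounds (otherwise the outermost half-pixel of foreground is lost)
    padded = np.pad(mask, 1)
    in_r = (out_r - half) / scale + centroid[0] + 1.0
    in_c = (out_c - half) / scale + centroid[1] + 1.0
    vals = ndimage.map_coordinates(
        padded.astype(np.float64),
        np.stack([in_r.ravel(), in_c.ravel()]),
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(side, side)
    lesion_id = getattr(lesion, "lesion_id", None)
    return NormalizedShapeImage(vals > 0.5, source_lesion_id=lesion_id)


def radial_polynomial(n: int, m: int, r) -> np.ndarray | float:
    """Radial Zernike polynomial ``R_nm(r)``.

    Defined for ``0 <= |m| <= n`` with ``n - |m|`` even, as the finite
    alternating factorial sum over ``k = 0 .. (n - |m|)/2``.
    """
    m = abs(int(m))
    n = int(n)
    if n < 0 or m > n:
        raise ValueError(f"need 0 <= |m| <= n, got n={n}, m={m}")
    if (n - m) % 2:
        raise ValueError(f"n - |m| must be even, got n={n}, m={m}")
    r_arr = np.asarray(r, dtype=np.float64)
    out = np.zeros_like(r_arr)
    for k in range((n - m) // 2 + 1):
        coeff = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        out += coeff * r_arr ** (n - 2 * k)
    return out if isinstance(r, np.ndarray) else float(out)


def zernike_basis_indices(max_order: int, nonnegative_only: bool = False) -> list[tuple[int, int]]:
    """All (n, m) index pairs with ``n <= max_order`` and ``n - |m|`` even."""
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    pairs = []
    for n in range(max_order + 1):
        start = 0 if nonnegative_only else -n
        for m in range(start, n + 1):
            if (n - abs(m)) % 2 == 0:
                pairs.append((n, m))
    return pairs


@lru_cache(maxsize=8)
def _basis(side: int, max_order: int, mapping: str):
    half = (side - 1) / 2.0
    rows, cols = np.mgrid[0:side, 0:side]
    if mapping == "circumscribed":
        c = side / math.sqrt(2.0)
    elif mapping == "inscribed":
        c = side / 2.0
    else:
        raise ValueError(f"unknown disc mapping: {mapping!r}")
    x = (cols - half) / c
    y = (rows - half) / c
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    # fractional disc coverage per pixel (8x8 subsampling): pixels straddling
    # the rim contribute partially, which sharpens the discrete orthogonality
    # of the basis under the inscribed mapping
    sub = (np.arange(8) + 0.5) / 8.0 - 0.5
    dr, dc = np.meshgrid(sub, sub, indexing="ij")
    r_sub = np.hypot(
        x[..., None] + dc.ravel() / c, y[..., None] + dr.ravel() / c
    )
    weights = (r_sub <= 1.0).mean(axis=-1)
    r_in = np.minimum(r, 1.0)
    area = 1.0 / c**2  # pixel area element in disc coordinates
    basis = {}
    for n, m in zernike_basis_indices(max_order):
        v = radial_polynomial(n, m, r_in) * np.exp(1j * m * theta)
        v.setflags(write=False)
        basis[(n, m)] = v
    weights.setflags(write=False)
    return basis, weights, area


def zernike_moments(
    img,
    max_order: int = DEFAULT_MAX_ORDER,
    mapping: str = "circumscribed",
) -> ZernikeMoments:
    """Discrete Zernike decomposition of a (normalized) shape image.

    Approximates ``Z_nm = (n+1)/pi * <f, V_nm>`` over pixels mapped into
    the unit disc, with the pixel-area element applied so that under the
    inscribed mapping a uniform full-disc image yields ``Z_00 ~ 1``.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    pixels = img.pixels if isinstance(img, NormalizedShapeImage) else np.asarray(img)
    f = pixels.astype(np.float64)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError("image must be a square 2D grid")
    side = f.shape[0]
    basis, weights, area = _basis(side, max_order, mapping)
    f_in = f * weights
    values = {}
    for (n, m), v in basis.items():
        values[(n, m)] = complex((n + 1) / math.pi * np.sum(f_in * np.conj(v)) * area)
    return ZernikeMoments(values=values, max_order=max_order, side=side, mapping=mapping)


def num_distinct_magnitudes(max_order: int) -> int:
    """Number of distinct ``|Z_nm|`` values for an expansion up to ``max_order``.

    Because ``|Z_{n,-m}| = |Z_{n,+m}|``, only repetitions ``m >= 0`` are
    distinct: ``((n+2)/2)^2`` for even ``n`` and ``(n+3)(n+1)/4`` for odd.
    """
    n = int(max_order)
    if n < 0:
        raise ValueError("order must be >= 0")
    if n % 2 == 0:
        return ((n + 2) // 2) ** 2
    return (n + 3) * (n + 1) // 4


def shape_feature_vector(moments: ZernikeMoments) -> np.ndarray:
    """Ordered vector of distinct moment magnitudes ``|Z_nm|``, ``m >= 0``.

    Ordering is (n ascending, m ascending); the length equals
    :func:`num_distinct_magnitudes` of the moments' max order (12 at
    order 5).
    """
    pairs = zernike_basis_indices(moments.max_order, nonnegative_only=True)
    return np.array([abs(moments.values[nm]) for nm in pairs], dtype=np.float64)


def feature_names(max_order: int = DEFAULT_MAX_ORDER) -> list[str]:
    """Column names (``z_n_m``) matching :func:`shape_feature_vector` order."""
    return [f"z_{n}_{m}" for n, m in zernike_basis_indices(max_order, nonnegative_only=True)]


def reconstruct(moments: ZernikeMoments) -> np.ndarray:
    """Truncated inverse Zernike transform (real part), for sanity checks."""
    basis, weights, _ = _basis(moments.side, moments.max_order, moments.mapping)
    out = np.zeros((moments.side, moments.side), dtype=np.complex128)
    for nm, v in basis.items():
        out += moments.values[nm] * v
    return np.where(weights > 0, out.real, 0.0)
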