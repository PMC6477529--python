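"""Fuzzy-logic intensity-histogram texture features for WMH lesions.

Lesion voxel intensities are despiked (winsorized at mean +/- 3 SD),
min-max normalized to [0, 1] using the 3D-linked lesion's extremes
(gMin, gMax), and accumulated into a histogram in which each normalized
value contributes fractional membership to its two nearest bins.  The
fuzzy split makes the histogram robust to quantization jitter from image
noise: a value sitting near a bin edge moves smoothly between bins
instead of flipping.  Histograms are normalized to unit total frequency
so lesions of different sizes are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FuzzyHistogram",
    "despike",
    "minmax_scale",
    "minmax_normalize",
    "fuzzy_assign",
    "fuzzy_frequencies",
    "texture_histogram",
    "texture_histograms_by_component",
]

DEFAULT_BINS = 5


@dataclass(frozen=True)
class FuzzyHistogram:
    """A fuzzy intensity histogram over ``n_bins`` equal-width bins on [0, 1]."""

    n_bins: int
    raw: np.ndarray
    normalized: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=np.float64))
        object.__setattr__(self, "normalized", np.asarray(self.normalized, dtype=np.float64))


def despike(intensities) -> np.ndarray:
    """Clamp (winsorize) values to within three standard deviations of the mean.

    Mean and SD (population, ddof=0) are computed once on the input; values
    are clamped, not excluded, so voxel counts are preserved.  A constant
    input (SD = 0) is returned unchanged.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("despike requires a non-empty intensity list")
    mu = float(x.mean())
    sd = float(x.std())
    return np.clip(x, mu - 3.0 * sd, mu + 3.0 * sd)


def minmax_scale(values, gmin: float, gmax: float) -> np.ndarray:
    """Map intensities to ``s = (f - gMin) / (gMax - gMin)`` in [0, 1].

    The degenerate case ``gMax == gMin`` (a perfectly flat lesion) maps
    every voxel to ``s = 0`` and emits a warning rather than failing.
    """
    x = np.asarray(values, dtype=np.float64)
    if gmax < gmin:
        raise ValueError("gMax must be >= gMin")
    if gmax == gmin:
        warnings.warn("gMax == gMin: flat intensity set, all s set to 0", stacklevel=2)
        return np.zeros_like(x)
    s = (x - gmin) / (gmax - gmin)
    return np.clip(s, 0.0, 1.0)


def minmax_normalize(lesion) -> np.ndarray:
    """Normalized intensities ``s`` of a 3D-linked lesion (its despiked voxels)."""
    return minmax_scale(lesion.intensities, lesion.gmin, lesion.gmax)


def _fuzzy_split(s: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lower bin index and complementary weights for each normalized value.

    Bin ``j`` has center ``(2j+1)/(2n)``; a value splits linearly between
    the two bins whose centers bracket it.  Values at or below the first
    center map entirely to bin 0, at or above the last center to bin n-1.
    """
    t = np.clip(s * n - 0.5, 0.0, float(n - 1))
    j0 = np.minimum(np.floor(t), n - 2).astype(np.intp)
    frac = t - j0
    return j0, 1.0 - frac, frac


def fuzzy_assign(s: float, n: int = DEFAULT_BINS) -> np.ndarray:
    """Fuzzy membership vector of a single normalized intensity over ``n`` bins.

    At most two entries are non-zero and they sum to 1.  Example: with
    five bins, ``s = 0.45`` contributes 0.25 to bin [0.2, 0.4] and 0.75
    to bin [0.4, 0.6].
    """
    if n < 2:
        raise ValueError("bin count must be >= 2")
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"normalized intensity must lie in [0, 1], got {s}")
    j0, w0, w1 = _fuzzy_split(np.asarray([s], dtype=np.float64), n)
    out = np.zeros(n, dtype=np.float64)
    out[j0[0]] += w0[0]
    out[j0[0] + 1] += w1[0]
    return out


def fuzzy_frequencies(s_values, n: int = DEFAULT_BINS) -> np.ndarray:
    """Raw fuzzy histogram: voxel-wise sum of fuzzy membership vectors."""
    if n < 2:
        raise ValueError("bin count must be >= 2")
    s = np.asarray(s_values, dtype=np.float64)
    if s.size and (s.min() < 0.0 or s.max() > 1.0):
        raise ValueError("normalized intensities must lie in [0, 1]")
    j0, w0, w1 = _fuzzy_split(s.ravel(), n)
    raw = np.bincount(j0, weights=w0, minlength=n) + np.bincount(
        j0 + 1, weights=w1, minlength=n
    )
    return raw


def texture_histogram(lesion, n: int = DEFAULT_BINS) -> FuzzyHistogram:
    """Fuzzy intensity histogram of a 3D-linked lesion.

    Raw frequencies sum to the voxel count; the normalized histogram is
    the raw one divided by the voxel count, summing to 1.
    """
    s = minmax_normalize(lesion)
    if s.size == 0:
        raise ValueError("cannot build a histogram for an empty lesion")
    raw = fuzzy_frequencies(s, n)
    return FuzzyHistogram(n_bins=n, raw=raw, normalized=raw / s.size, n_voxels=int(s.size))


def texture_histograms_by_component(lesion3d, n: int = DEFAULT_BINS) -> list[FuzzyHistogram]:
    """Per-2D-component histograms normalized by the parent lesion's gMin/gMax.

    Individual lesion images on each slice get their own histogram, but the
    intensity scale (and despiking) comes from the parent 3D-linked lesion,
    so slices of one lesion share a common reference range.
    """
    out = []
    for comp_int in lesion3d.component_intensities:
        s = minmax_scale(comp_int, lesion3d.gmin, lesion3d.gmax)
        if s.size == 0:
            raise ValueError("cannot build a histogram for an empty component")
        raw = fuzzy_frequencies(s, n)
        out.append(FuzzyHistogram(n_bins=n, raw=raw, normalized=raw / s.size, n_voxels=int(s.size)))
    return out
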