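"""Radial chromatic-contrast curves per histogram quadrant.

The chromatic contrast of a bin is the Euclidean distance of its center to
the plane origin, rounded to 4 decimal places; on the default 128x128 grid
over [-2, 2] this yields 1,464 unique contrast levels.  A contrast curve
sums histogram mass over the bins of a quadrant subset at each level and
divides by the number of bins in the subset, so quadrants of different
sizes (e.g. Q1 vs Q2+Q3+Q4) are directly comparable.  Curves may finally
be smoothed with a 1-D Gaussian (sigma = 10 samples) along the level index.

Quadrants are defined by bin-center sign: Q1 = (+x, +y), Q2 = (-x, +y),
Q3 = (-x, -y), Q4 = (+x, -y).  On the default grid the centers are odd
multiples of 1/64, so no center lies on an axis and membership is total.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .joint_histograms import JointHistogram, N_BINS_DEFAULT, RANGE_DEFAULT, bin_edges

__all__ = [
    "QuadrantSet",
    "ContrastCurve",
    "DifferenceCurve",
    "round_contrast",
    "enumerate_contrast_levels",
    "contrast_level_index",
    "contrast_curve",
    "smooth_curve",
    "curve_difference",
    "warm_excess_statistic",
]

QUADRANT_NAMES = ("Q1", "Q2", "Q3", "Q4")


def round_contrast(values: np.ndarray | float, decimals: int = 4) -> np.ndarray:
    """Round half away from zero to ``decimals`` decimal places.

    This is MATLAB-style ``round(x, 4)``; for contrast values >= 1 (the grid
    diagonal reaches 2*sqrt(2)) it coincides with rounding to the 4th
    significant digit.
    """
    v = np.asarray(values, dtype=np.float64)
    scale = 10.0**decimals
    return np.copysign(np.floor(np.abs(v) * scale + 0.5), v) / scale


@lru_cache(maxsize=8)
def _grid_cache(n_bins: int, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(levels, level_index grid, centers) for one bin geometry."""
    edges = bin_edges(n_bins, (lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    rounded = round_contrast(np.hypot(cx, cy))
    levels = np.unique(rounded)
    index = np.searchsorted(levels, rounded)
    index.setflags(write=False)
    levels.setflags(write=False)
    centers.setflags(write=False)
    return levels, index, centers


def enumerate_contrast_levels(
    n_bins: int = N_BINS_DEFAULT, vrange: tuple[float, float] = RANGE_DEFAULT
) -> np.ndarray:
    """Sorted unique rounded bin-center distances to the origin.

    The default grid yields exactly 1,464 levels.
    """
    return _grid_cache(n_bins, *vrange)[0].copy()


def contrast_level_index(
    n_bins: int = N_BINS_DEFAULT, vrange: tuple[float, float] = RANGE_DEFAULT
) -> np.ndarray:
    """(n_bins, n_bins) map from bin (ix, iy) to contrast-level index."""
    return _grid_cache(n_bins, *vrange)[1]


@dataclass(frozen=True)
class QuadrantSet:
    """A non-empty subset of the four histogram quadrants."""

    included: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "included", frozenset(self.included))
        if not self.included:
            raise ValueError("quadrant set must be non-empty")
        unknown = self.included - set(QUADRANT_NAMES)
        if unknown:
            raise ValueError(f"unknown quadrants: {sorted(unknown)}")

    @classmethod
    def of(cls, *names: str) -> "QuadrantSet":
        return cls(frozenset(names))

    @classmethod
    def complement_of(cls, other: "QuadrantSet") -> "QuadrantSet":
        return cls(frozenset(QUADRANT_NAMES) - other.included)

    def mask(
        self, n_bins: int = N_BINS_DEFAULT, vrange: tuple[float, float] = RANGE_DEFAULT
    ) -> np.ndarray:
        """Boolean (n_bins, n_bins) membership grid by bin-center sign."""
        centers = _grid_cache(n_bins, *vrange)[2]
        if np.any(centers == 0.0):
            raise ValueError("a bin center lies on an axis; quadrant membership undefined")
        cx, cy = np.meshgrid(centers, centers, indexing="ij")
        per_quad = {
            "Q1": (cx > 0) & (cy > 0),
            "Q2": (cx < 0) & (cy > 0),
            "Q3": (cx < 0) & (cy < 0),
            "Q4": (cx > 0) & (cy < 0),
        }
        out = np.zeros_like(cx, dtype=bool)
        for q in self.included:
            out |= per_quad[q]
        return out

    def n_bins(
        self, n_bins: int = N_BINS_DEFAULT, vrange: tuple[float, float] = RANGE_DEFAULT
    ) -> int:
        return int(self.mask(n_bins, vrange).sum())

    @property
    def label(self) -> str:
        return "".join(q[1] for q in sorted(self.included))


WARM = QuadrantSet.of("Q1")
REST = QuadrantSet.complement_of(WARM)
BLUE = QuadrantSet.of("Q3")


@dataclass
class ContrastCurve:
    """Relative pixel frequency per bin as a function of radial contrast."""

    contrast_values: np.ndarray
    density: np.ndarray
    quadrants: QuadrantSet
    smoothed: bool = False
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.contrast_values = np.asarray(self.contrast_values, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.contrast_values.shape != self.density.shape:
            raise ValueError("contrast grid and density length mismatch")
        if not np.all(np.diff(self.contrast_values) > 0):
            raise ValueError("contrast values must be strictly increasing")
        if (self.density < -1e-15).any():
            raise ValueError("negative curve density")

    def same_grid(self, other: "ContrastCurve | DifferenceCurve") -> bool:
        return np.array_equal(self.contrast_values, other.contrast_values)


@dataclass
class DifferenceCurve:
    """Pointwise signed difference between two contrast curves."""

    contrast_values: np.ndarray
    delta: np.ndarray
    smoothed: bool = False


def contrast_curve(
    hist: JointHistogram,
    quads: QuadrantSet,
    vrange: tuple[float, float] = RANGE_DEFAULT,
) -> ContrastCurve:
    """Sum histogram mass per contrast level over a quadrant subset.

    The sums are divided by the number of grid bins in the subset so that
    differently sized quadrant sets can be compared.
    """
    if not hist.normalized:
        raise ValueError("contrast_curve expects a normalized histogram")
    n = hist.counts.shape[0]
    levels = enumerate_contrast_levels(n, vrange)
    index = contrast_level_index(n, vrange)
    mask = quads.mask(n, vrange)
    sums = np.bincount(index[mask], weights=hist.counts[mask], minlength=levels.size)
    return ContrastCurve(
        contrast_values=levels,
        density=sums / mask.sum(),
        quadrants=quads,
        smoothed=False,
    )


def smooth_curve(curve: ContrastCurve, sigma: float = 10.0) -> ContrastCurve:
    """Convolve with a unit-sum Gaussian along the sample index.

    The kernel is truncated at 4 sigma and renormalized; the boundary
    reflects, preserving total mass for interior-supported curves.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if curve.smoothed:
        raise ValueError("curve is already smoothed")
    density = gaussian_filter1d(curve.density, sigma, mode="reflect", truncate=4.0)
    return replace(curve, density=density, smoothed=True, sigma=sigma)


def curve_difference(a: ContrastCurve, b: ContrastCurve) -> DifferenceCurve:
    """Pointwise a - b on a shared contrast grid and smoothing state."""
    if not a.same_grid(b):
        raise ValueError("curves are on different contrast grids")
    if a.smoothed != b.smoothed:
        raise ValueError("curves differ in smoothing state")
    return DifferenceCurve(
        contrast_values=a.contrast_values.copy(),
        delta=a.density - b.density,
        smoothed=a.smoothed,
    )


def warm_excess_statistic(
    quad_curves: list[ContrastCurve], rest_curves: list[ContrastCurve]
) -> float:
    """Contrast-weighted excess of one quadrant set over its complement.

    Computes the first moment over contrast of the mean difference curve,
    ``sum_c c * (mean_quad(c) - mean_rest(c))`` — the difference in
    mass-weighted mean contrast per grid bin.  Positive when the first
    quadrant set carries relatively more high-contrast mass.  Curves are
    used unsmoothed (smoothing is a display operation and approximately
    preserves this moment).

    The same function serves the "blue" control quadrant by passing Q3
    curves and their complement.
    """
    if not quad_curves or len(quad_curves) != len(rest_curves):
        raise ValueError("need equal-length non-empty curve lists")
    grid = quad_curves[0].contrast_values
    for c in list(quad_curves) + list(rest_curves):
        if not np.array_equal(c.contrast_values, grid):
            raise ValueError("curves are on different contrast grids")
        if c.smoothed:
            raise ValueError("statistic is defined on unsmoothed curves")
    mean_q = np.mean([c.density for c in quad_curves], axis=0)
    mean_r = np.mean([c.density for c in rest_curves], axis=0)
    return float(np.sum(grid * (mean_q - mean_r)))
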