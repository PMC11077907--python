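"""Percentile bootstrap confidence bands for mean contrast curves.

The corpus mean curve is resampled nonparametrically: draw N per-image
curves with replacement (N = corpus size), average, repeat ``n_boot``
times, and at each contrast level take order statistics of the resampled
means.  For 1,000 resamples at 95% the band is the 25th and 975th sorted
values per level.  "Sorting the curves" is interpreted pointwise per
contrast level — the only interpretation that yields a well-defined
envelope, as no total order on whole curves is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contrast_curves import ContrastCurve

__all__ = ["CurveBand", "bootstrap_band", "percentile_ranks"]


@dataclass
class CurveBand:
    """Bootstrap percentile envelope around a mean contrast curve."""

    contrast_values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mean: np.ndarray
    n_boot: int
    level: float
    seed: int
    lower_rank: int  # 1-based order statistic used per level
    upper_rank: int

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("band lower bound exceeds upper bound")


def percentile_ranks(n_boot: int, level: float) -> tuple[int, int]:
    """1-based order statistics (k, n_boot - k) with k = floor(n_boot*(1-level)/2).

    For 1,000 resamples at 95% this selects the 25th and 975th sorted values.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    # epsilon guards the floor against float artifacts (e.g. 1000*0.2/2)
    k = math.floor(n_boot * (1.0 - level) / 2.0 + 1e-9)
    k = max(k, 1)
    if n_boot - k < k:
        raise ValueError("n_boot too small for the requested level")
    return k, n_boot - k


def bootstrap_band(
    curves: list[ContrastCurve],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> CurveBand:
    """Percentile bootstrap band for the mean of per-image contrast curves.

    Resampling indices are drawn once per bootstrap replicate from a
    ``numpy.random.default_rng(seed)`` stream, so bands are bit-identical
    across runs for a fixed seed.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    grid = curves[0].contrast_values
    for c in curves[1:]:
        if not np.array_equal(c.contrast_values, grid):
            raise ValueError("curves are on different contrast grids")
    stacked = np.stack([c.density for c in curves])  # (N, L)
    n = stacked.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = stacked[idx].mean(axis=1)  # (n_boot, L)
    boot_means.sort(axis=0)
    k_lo, k_hi = percentile_ranks(n_boot, level)
    return CurveBand(
        contrast_values=grid.copy(),
        lower=boot_means[k_lo - 1].copy(),
        upper=boot_means[k_hi - 1].copy(),
        mean=stacked.mean(axis=0),
        n_boot=n_boot,
        level=level,
        seed=seed,
        lower_rank=k_lo,
        upper_rank=k_hi,
    )
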