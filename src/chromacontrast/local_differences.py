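"""Local chromatic and achromatic difference statistics (CIELUV-based).

Each image is reduced to two numbers: the mean local chromatic difference
(Euclidean distance between a pixel and each of its 8 neighbors in the
(u', v') chromaticity plane) and the mean local achromatic difference
(same neighborhood, distances in the L channel).  Images are first
center-cropped to a square and resized to 256x256 with bicubic
interpolation so the statistics are comparable across image sizes.
Across a corpus, the two per-image statistics are compared by Pearson
correlation.

The 8-neighborhood is undefined on the 1-pixel border; border pixels are
excluded from the per-image means rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize

from .colorspace import LUVImage, RasterImage, srgb_to_luv

__all__ = [
    "LocalDiffRecord",
    "CorrelationReport",
    "central_crop_resize",
    "local_difference_maps",
    "image_local_diffs",
    "correlate_diffs",
    "records_to_csv",
    "records_from_csv",
]


@dataclass
class LocalDiffRecord:
    """Per-image mean local chromatic and achromatic differences."""

    source_id: str
    chromatic_diff: float
    achromatic_diff: float
    group: str = ""

    def __post_init__(self) -> None:
        for name in ("chromatic_diff", "achromatic_diff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")


@dataclass
class CorrelationReport:
    """Pearson correlation between chromatic and achromatic differences."""

    group: str
    n: int
    r: float
    p: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 or not 0.0 <= self.p <= 1.0:
            raise ValueError("invalid correlation report")


def central_crop_resize(img: RasterImage, side: int = 256) -> RasterImage:
    """Center-crop to a square (offsets floored) and bicubic-resize to side**2.

    Anti-aliasing is applied when downscaling, matching common resize
    implementations; output values are clipped back to [0, 1].
    """
    h, w = img.shape
    m = min(h, w)
    r0 = (h - m) // 2
    c0 = (w - m) // 2
    crop = img.pixels[r0 : r0 + m, c0 : c0 + m]
    if m == side:
        out = crop.copy()
    else:
        out = resize(
            crop,
            (side, side, 3),
            order=3,
            mode="reflect",
            anti_aliasing=m > side,
            preserve_range=True,
        )
        out = np.clip(out, 0.0, 1.0)
    return RasterImage(pixels=out, source_id=img.source_id, bit_depth=img.bit_depth)


_NEIGHBOR_OFFSETS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def local_difference_maps(luv: LUVImage) -> tuple[np.ndarray, np.ndarray]:
    """Per-interior-pixel mean 8-neighbor distances in (u', v') and in L.

    Returns ``(chromatic, achromatic)`` maps of shape ``(H-2, W-2)``.
    """
    h, w = luv.shape
    if h < 3 or w < 3:
        raise ValueError("image must be at least 3x3 for an 8-neighborhood")
    u, v, L = luv.u, luv.v, luv.L
    uc = u[1:-1, 1:-1]
    vc = v[1:-1, 1:-1]
    lc = L[1:-1, 1:-1]
    chrom = np.zeros_like(uc)
    achrom = np.zeros_like(lc)
    for di, dj in _NEIGHBOR_OFFSETS:
        un = u[1 + di : h - 1 + di, 1 + dj : w - 1 + dj]
        vn = v[1 + di : h - 1 + di, 1 + dj : w - 1 + dj]
        ln = L[1 + di : h - 1 + di, 1 + dj : w - 1 + dj]
        chrom += np.hypot(uc - un, vc - vn)
        achrom += np.abs(lc - ln)
    return chrom / 8.0, achrom / 8.0


def image_local_diffs(
    img: RasterImage,
    group: str = "",
    side: int = 256,
    l_mode: str = "Y",
) -> LocalDiffRecord:
    """Full chain: central crop/resize → (L, u', v') → 8-neighbor maps → means."""
    prepared = central_crop_resize(img, side=side)
    luv = srgb_to_luv(prepared, l_mode=l_mode)
    chrom, achrom = local_difference_maps(luv)
    return LocalDiffRecord(
        source_id=img.source_id,
        chromatic_diff=float(chrom.mean()),
        achromatic_diff=float(achrom.mean()),
        group=group,
    )


def correlate_diffs(
    records: list[LocalDiffRecord],
    group: str | None = None,
    alternative: str = "two-sided",
) -> CorrelationReport:
    """Pearson r between chromatic and achromatic differences within a group.

    The p-value uses the t approximation (two-sided by default; a one-sided
    alternative can be requested explicitly).
    """
    if group is not None:
        records = [r for r in records if r.group == group]
    if len(records) < 3:
        raise ValueError("need at least 3 records to correlate")
    x = np.array([r.chromatic_diff for r in records])
    y = np.array([r.achromatic_diff for r in records])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y, alternative=alternative)
    return CorrelationReport(
        group=group if group is not None else (records[0].group or ""),
        n=len(records),
        r=float(res.statistic),
        p=float(res.pvalue),
    )


def records_to_csv(records: list[LocalDiffRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "source_id": [r.source_id for r in records],
            "group": [r.group for r in records],
            "chromatic_diff": [r.chromatic_diff for r in records],
            "achromatic_diff": [r.achromatic_diff for r in records],
        }
    ).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[LocalDiffRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        LocalDiffRecord(
            source_id=str(row.source_id),
            chromatic_diff=float(row.chromatic_diff),
            achromatic_diff=float(row.achromatic_diff),
            group=str(row.group),
        )
        for row in df.itertuples()
    ]
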