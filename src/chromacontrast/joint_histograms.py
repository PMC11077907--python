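"""Joint 2-D histograms and chromograms over the cardinal DKL planes.

Each image yields a 128x128 histogram per plane pair on the range [-2, 2],
normalized by the image's total pixel count so the histogram is independent
of image size.  Corpus summaries are binwise unweighted means of the
per-image histograms.  A "chromogram" colors each occupied bin with the
mean sRGB value of the pixels that fall into it.

Bin geometry: 128 equal-width bins per axis with edges at -2 + k*(4/128);
bins are half-open [edge_k, edge_{k+1}) except the last, which is closed.
Pixels with |coordinate| > 2 are excluded from the grid but counted (with
the default gamut-calibrated scaling this set is empty for in-gamut input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorspace import DKLImage, RasterImage

__all__ = [
    "PlanePair",
    "JointHistogram",
    "Chromogram",
    "ISOLUMINANT",
    "LM_VS_ACH",
    "S_VS_ACH",
    "PLANES",
    "compute_joint_histogram",
    "mean_histogram",
    "compute_chromogram",
    "masked_histogram",
    "histogram_to_csv",
    "histogram_from_csv",
    "chromogram_to_png",
]

N_BINS_DEFAULT = 128
RANGE_DEFAULT = (-2.0, 2.0)


@dataclass(frozen=True)
class PlanePair:
    """One of the three cardinal DKL plane pairs (x axis, y axis)."""

    name: str
    x_axis: str
    y_axis: str

    def __post_init__(self) -> None:
        if self.x_axis == self.y_axis:
            raise ValueError("plane axes must differ")

    def coords(self, dkl: DKLImage) -> tuple[np.ndarray, np.ndarray]:
        return dkl.axis(self.x_axis).ravel(), dkl.axis(self.y_axis).ravel()


ISOLUMINANT = PlanePair("LM_vs_S", "lm", "s")
LM_VS_ACH = PlanePair("LM_vs_ACH", "lm", "ach")
S_VS_ACH = PlanePair("S_vs_ACH", "s", "ach")
PLANES: dict[str, PlanePair] = {p.name: p for p in (ISOLUMINANT, LM_VS_ACH, S_VS_ACH)}


def bin_edges(n_bins: int = N_BINS_DEFAULT, vrange: tuple[float, float] = RANGE_DEFAULT) -> np.ndarray:
    lo, hi = vrange
    return lo + np.arange(n_bins + 1) * ((hi - lo) / n_bins)


@dataclass
class JointHistogram:
    """Normalized (or raw-count) 2-D histogram of one DKL plane.

    ``counts[i, j]`` covers x-bin ``i`` and y-bin ``j``.  For a normalized
    histogram, ``counts.sum() + out_of_range_fraction == 1``.
    """

    plane: PlanePair
    counts: np.ndarray
    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    n_pixels_total: float
    n_pixels_out_of_range: float = 0.0
    normalized: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (self.counts < 0).any():
            raise ValueError("negative bin counts")
        for e in (self.bin_edges_x, self.bin_edges_y):
            if not np.all(np.diff(e) > 0):
                raise ValueError("bin edges must be strictly increasing")
        if self.normalized and self.n_pixels_total > 0:
            total = self.counts.sum() + self.out_of_range_fraction
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"normalized histogram sums to {total!r}, not 1")

    @property
    def out_of_range_fraction(self) -> float:
        if self.n_pixels_total == 0:
            return 0.0
        return self.n_pixels_out_of_range / self.n_pixels_total

    @property
    def bin_centers_x(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_x[:-1] + self.bin_edges_x[1:])

    @property
    def bin_centers_y(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_y[:-1] + self.bin_edges_y[1:])

    def same_binning(self, other: "JointHistogram") -> bool:
        return (
            self.plane == other.plane
            and np.array_equal(self.bin_edges_x, other.bin_edges_x)
            and np.array_equal(self.bin_edges_y, other.bin_edges_y)
        )


@dataclass
class Chromogram:
    """Per-bin mean sRGB color of the pixels falling in each histogram bin."""

    plane: PlanePair
    mean_color: np.ndarray  # (n, n, 3); NaN where unsupported
    support: np.ndarray  # (n, n) bool
    bin_edges_x: np.ndarray = field(default_factory=lambda: bin_edges())
    bin_edges_y: np.ndarray = field(default_factory=lambda: bin_edges())

    def __post_init__(self) -> None:
        defined = np.isfinite(self.mean_color).all(axis=-1)
        if not np.array_equal(defined, self.support):
            raise ValueError("mean_color must be defined exactly on the support")


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bin index per value; the last bin is closed (numpy convention)."""
    idx = np.searchsorted(edges, values, side="right") - 1
    # values exactly at the top edge belong to the last bin
    idx[values == edges[-1]] = len(edges) - 2
    return idx


def compute_joint_histogram(
    dkl: DKLImage,
    plane: PlanePair,
    n_bins: int = N_BINS_DEFAULT,
    vrange: tuple[float, float] = RANGE_DEFAULT,
) -> JointHistogram:
    """Per-image joint histogram, normalized by the image's pixel count.

    Out-of-range pixels (|coordinate| beyond the range) are excluded from
    the grid but reported in ``n_pixels_out_of_range``, so the histogram
    sum plus the out-of-range fraction is exactly 1.
    """
    x, y = plane.coords(dkl)
    n_total = x.size
    if n_total == 0:
        raise ValueError("empty image")
    lo, hi = vrange
    in_range = (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)
    counts, ex, ey = np.histogram2d(
        x[in_range], y[in_range], bins=n_bins, range=[[lo, hi], [lo, hi]]
    )
    n_out = n_total - int(in_range.sum())
    if n_out:
        import logging

        logging.getLogger("chromacontrast").info(
            "%d/%d pixels outside [%g, %g] excluded from histogram", n_out, n_total, lo, hi
        )
    return JointHistogram(
        plane=plane,
        counts=counts / n_total,
        bin_edges_x=ex,
        bin_edges_y=ey,
        n_pixels_total=n_total,
        n_pixels_out_of_range=n_out,
        normalized=True,
    )


def mean_histogram(hists: list[JointHistogram]) -> JointHistogram:
    """Binwise unweighted mean across images (not pixel-pooled)."""
    if not hists:
        raise ValueError("no histograms to average")
    first = hists[0]
    for h in hists[1:]:
        if not first.same_binning(h):
            raise ValueError("histograms differ in plane or binning")
        if not h.normalized:
            raise ValueError("mean_histogram requires normalized histograms")
    if not first.normalized:
        raise ValueError("mean_histogram requires normalized histograms")
    counts = np.mean([h.counts for h in hists], axis=0)
    n_total = float(sum(h.n_pixels_total for h in hists))
    mean_oor = float(np.mean([h.out_of_range_fraction for h in hists]))
    return JointHistogram(
        plane=first.plane,
        counts=counts,
        bin_edges_x=first.bin_edges_x.copy(),
        bin_edges_y=first.bin_edges_y.copy(),
        n_pixels_total=n_total,
        n_pixels_out_of_range=mean_oor * n_total,
        normalized=True,
    )


def compute_chromogram(
    img: RasterImage,
    dkl: DKLImage,
    plane: PlanePair,
    n_bins: int = N_BINS_DEFAULT,
    vrange: tuple[float, float] = RANGE_DEFAULT,
) -> Chromogram:
    """Mean sRGB color per occupied bin; averaging is done on encoded values."""
    if img.shape != dkl.shape:
        raise ValueError(f"image {img.shape} and DKL {dkl.shape} are misaligned")
    x, y = plane.coords(dkl)
    rgb = img.pixels.reshape(-1, 3)
    lo, hi = vrange
    in_range = (x >= lo) & (x <= hi) & (y >= lo) & (y <= hi)
    ex = bin_edges(n_bins, vrange)
    ix = _bin_index(x[in_range], ex)
    iy = _bin_index(y[in_range], ex)
    flat = ix * n_bins + iy
    counts = np.bincount(flat, minlength=n_bins * n_bins).astype(np.float64)
    sums = np.stack(
        [np.bincount(flat, weights=rgb[in_range, c], minlength=n_bins * n_bins) for c in range(3)],
        axis=-1,
    )
    support = counts > 0
    mean = np.full((n_bins * n_bins, 3), np.nan)
    mean[support] = sums[support] / counts[support, None]
    return Chromogram(
        plane=plane,
        mean_color=mean.reshape(n_bins, n_bins, 3),
        support=support.reshape(n_bins, n_bins),
        bin_edges_x=ex,
        bin_edges_y=ex.copy(),
    )


def masked_histogram(
    dkl: DKLImage,
    mask: np.ndarray,
    plane: PlanePair,
    n_bins: int = N_BINS_DEFAULT,
    vrange: tuple[float, float] = RANGE_DEFAULT,
) -> JointHistogram:
    """Histogram restricted to mask-true pixels, normalized by mask pixel count."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dkl.shape:
        raise ValueError(f"mask {mask.shape} and DKL {dkl.shape} are misaligned")
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise ValueError("empty mask")
    sub = DKLImage(
        ach=dkl.ach[mask].reshape(1, -1),
        lm=dkl.lm[mask].reshape(1, -1),
        s=dkl.s[mask].reshape(1, -1),
    )
    return compute_joint_histogram(sub, plane, n_bins=n_bins, vrange=vrange)


# -- serialization -----------------------------------------------------------


def histogram_to_csv(hist: JointHistogram, path: str | Path) -> None:
    """Long-format CSV: bin_x_center, bin_y_center, value (nonzero bins only)."""
    cx = hist.bin_centers_x
    cy = hist.bin_centers_y
    ix, iy = np.nonzero(hist.counts)
    df = pd.DataFrame(
        {
            "bin_x_center": cx[ix],
            "bin_y_center": cy[iy],
            "value": hist.counts[ix, iy],
        }
    )
    header = (
        f"# plane={hist.plane.name} x={hist.plane.x_axis} y={hist.plane.y_axis} "
        f"n_bins={hist.counts.shape[0]} range={hist.bin_edges_x[0]}:{hist.bin_edges_x[-1]} "
        f"n_pixels_total={hist.n_pixels_total} n_out_of_range={hist.n_pixels_out_of_range} "
        f"normalized={hist.normalized}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def histogram_from_csv(path: str | Path) -> JointHistogram:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    plane = PLANES[meta["plane"]]
    n_bins = int(meta["n_bins"])
    lo, hi = (float(t) for t in meta["range"].split(":"))
    ex = bin_edges(n_bins, (lo, hi))
    counts = np.zeros((n_bins, n_bins))
    ix = _bin_index(df["bin_x_center"].to_numpy(), ex)
    iy = _bin_index(df["bin_y_center"].to_numpy(), ex)
    counts[ix, iy] = df["value"].to_numpy()
    return JointHistogram(
        plane=plane,
        counts=counts,
        bin_edges_x=ex,
        bin_edges_y=ex.copy(),
        n_pixels_total=float(meta["n_pixels_total"]),
        n_pixels_out_of_range=float(meta["n_out_of_range"]),
        normalized=meta["normalized"] == "True",
    )


def chromogram_to_png(chromo: Chromogram, path: str | Path, empty_value: float = 1.0) -> None:
    """Write the chromogram as an 8-bit PNG; empty bins are rendered white.

    Rows are y bins from top (+) to bottom (-), columns x bins left (-) to
    right (+), matching a conventional plot orientation.
    """
    img = np.where(chromo.support[..., None], chromo.mean_color, empty_value)
    img = np.transpose(img, (1, 0, 2))[::-1]  # (y, x, 3), y increasing upward
    iio.imwrite(Path(path), (np.clip(img, 0, 1) * 255).round().astype(np.uint8))
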