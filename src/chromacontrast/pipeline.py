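"""End-to-end two-corpus analysis: ingest → DKL → histograms → curves →
bootstrap bands → quadrant statistics → CIELUV local differences.

The pipeline compares two image corpora (e.g. paintings vs photographs).
For each corpus and each requested DKL plane it computes per-image joint
histograms, the corpus-mean histogram and chromogram, contrast curves for
a focus quadrant versus the remaining quadrants with percentile bootstrap
bands, their difference curve, and a scalar contrast-excess statistic.
The isoluminant-plane Q1 statistic is the headline "warm excess"; the
S-vs-achromatic-plane Q3 statistic serves as the "blue" control.  Each
image also contributes a local chromatic/achromatic difference record;
the two are correlated per corpus.

Unreadable images are skipped with a logged warning and counted in the
report; an empty corpus is fatal.  Unequal corpus sizes are handled with
per-corpus bootstrap at each corpus's own N.  All randomness derives from
the single configured seed, so a re-run with the same config produces a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap_stats import CurveBand, bootstrap_band
from .colorspace import ColorSpaceConfig, RasterImage, read_image, srgb_to_dkl
from .contrast_curves import (
    ContrastCurve,
    QuadrantSet,
    contrast_curve,
    curve_difference,
    smooth_curve,
    warm_excess_statistic,
)
from .joint_histograms import (
    PLANES,
    Chromogram,
    JointHistogram,
    chromogram_to_png,
    compute_chromogram,
    compute_joint_histogram,
    histogram_to_csv,
    mean_histogram,
)
from .local_differences import (
    LocalDiffRecord,
    correlate_diffs,
    image_local_diffs,
    records_to_csv,
)

logger = logging.getLogger("chromacontrast")

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")

#: Per-plane focus quadrant: Q1 (warm, red–orange–yellow) in the planes with
#: an L/M axis; Q3 (blue) in the S-vs-achromatic control plane.
DEFAULT_FOCUS = {"LM_vs_S": "Q1", "LM_vs_ACH": "Q1", "S_vs_ACH": "Q3"}


@dataclass
class RunConfig:
    """Configuration of a full two-corpus run."""

    corpus_a_dir: str
    corpus_b_dir: str
    output_dir: str
    label_a: str = "corpus_a"
    label_b: str = "corpus_b"
    planes: list[str] = field(default_factory=lambda: list(PLANES))
    focus_quadrants: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FOCUS))
    warm_plane: str = "LM_vs_S"
    blue_plane: str = "S_vs_ACH"
    blue_control_reference: list[str] = field(default_factory=lambda: ["Q2"])
    n_boot: int = 1000
    level: float = 0.95
    sigma: float = 10.0
    seed: int = 0
    colorspace_file: str | None = None
    write_plots: bool = True

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in self.planes:
            if name not in PLANES:
                raise ValueError(f"unknown plane {name!r}")
        for d, label in ((self.corpus_a_dir, "corpus_a_dir"), (self.corpus_b_dir, "corpus_b_dir")):
            p = Path(d)
            if not p.is_dir():
                raise ValueError(f"{label} {d!r} is not a directory")
            if not any(f.suffix.lower() in IMAGE_SUFFIXES for f in p.iterdir()):
                raise ValueError(f"{label} {d!r} contains no readable images")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "corpus_a_dir": str(self.corpus_a_dir),
            "corpus_b_dir": str(self.corpus_b_dir),
            "output_dir": str(self.output_dir),
            "label_a": self.label_a,
            "label_b": self.label_b,
            "planes": list(self.planes),
            "focus_quadrants": dict(self.focus_quadrants),
            "warm_plane": self.warm_plane,
            "blue_plane": self.blue_plane,
            "n_boot": self.n_boot,
            "level": self.level,
            "blue_control_reference": list(self.blue_control_reference),
            "sigma": self.sigma,
            "seed": self.seed,
            "colorspace_file": self.colorspace_file,
        }


@dataclass
class AnalysisReport:
    """Machine-readable result of :func:`run_analysis`."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=2)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def load_corpus(directory: str | Path) -> tuple[list[RasterImage], int]:
    """Read all PNG/TIFF images in a directory; returns (images, n_skipped)."""
    files = sorted(
        f for f in Path(directory).iterdir() if f.suffix.lower() in IMAGE_SUFFIXES
    )
    images: list[RasterImage] = []
    skipped = 0
    for f in files:
        try:
            images.append(read_image(f))
        except Exception as exc:  # noqa: BLE001 - skip policy is deliberate
            logger.warning("skipping unreadable image %s: %s", f.name, exc)
            skipped += 1
    if not images:
        raise ValueError(f"no readable images in {directory}")
    return images, skipped


def _mean_chromogram(
    images: list[RasterImage], dkls, plane
) -> Chromogram:
    """Corpus chromogram: per-bin mean color pooled over all images' pixels."""
    n = 128
    counts = np.zeros(n * n)
    sums = np.zeros((n * n, 3))
    for img, dkl in zip(images, dkls):
        ch = compute_chromogram(img, dkl, plane)
        c = ch.support.reshape(-1)
        # recover per-image sums from means and per-image counts
        per_counts = np.zeros(n * n)
        x, y = plane.coords(dkl)
        in_range = (np.abs(x) <= 2) & (np.abs(y) <= 2)
        hist = np.histogram2d(x[in_range], y[in_range], bins=n, range=[[-2, 2], [-2, 2]])[0]
        per_counts = hist.reshape(-1)
        sums[c] += ch.mean_color.reshape(-1, 3)[c] * per_counts[c, None]
        counts += per_counts
    support = counts > 0
    mean = np.full((n * n, 3), np.nan)
    mean[support] = sums[support] / counts[support, None]
    return Chromogram(
        plane=plane,
        mean_color=mean.reshape(n, n, 3),
        support=support.reshape(n, n),
    )


def _curves_frame(
    levels: np.ndarray,
    focus_band: CurveBand,
    rest_band: CurveBand,
    sigma: float,
) -> pd.DataFrame:
    """Display table: smoothed mean curves with smoothed band bounds."""

    def smooth(density: np.ndarray) -> np.ndarray:
        from scipy.ndimage import gaussian_filter1d

        return gaussian_filter1d(density, sigma, mode="reflect", truncate=4.0)

    return pd.DataFrame(
        {
            "contrast": levels,
            "focus_mean": smooth(focus_band.mean),
            "focus_lower": smooth(focus_band.lower),
            "focus_upper": smooth(focus_band.upper),
            "rest_mean": smooth(rest_band.mean),
            "rest_lower": smooth(rest_band.lower),
            "rest_upper": smooth(rest_band.upper),
            "difference": smooth(focus_band.mean) - smooth(rest_band.mean),
        }
    )


def _plot_histogram(hist: JointHistogram, path: Path, title: str) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    # darker gray = more pixels
    img = hist.counts.T[::-1]
    with np.errstate(divide="ignore"):
        shade = np.log10(img + 1e-7)
    ax.imshow(shade, cmap="gray_r", extent=[-2, 2, -2, 2])
    ax.set_xlabel(hist.plane.x_axis)
    ax.set_ylabel(hist.plane.y_axis)
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_curves(frame: pd.DataFrame, path: Path, title: str) -> None:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
    c = frame["contrast"]
    ax1.fill_between(c, frame["focus_lower"], frame["focus_upper"], color="red", alpha=0.2)
    ax1.fill_between(c, frame["rest_lower"], frame["rest_upper"], color="gray", alpha=0.3)
    ax1.plot(c, frame["focus_mean"], "r-", lw=1, label="focus quadrant")
    ax1.plot(c, frame["rest_mean"], "k-", lw=1, label="other quadrants")
    ax1.set_xlabel("chromatic contrast")
    ax1.set_ylabel("relative frequency / bin")
    ax1.legend(fontsize=7)
    ax2.plot(c, frame["difference"], "-", lw=1)
    ax2.axhline(0, color="0.7", lw=0.5)
    ax2.set_xlabel("chromatic contrast")
    ax2.set_ylabel("difference")
    fig.suptitle(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_scatter(
    records_a: list[LocalDiffRecord],
    records_b: list[LocalDiffRecord],
    labels: tuple[str, str],
    path: Path,
) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 4))
    for recs, label, color in zip((records_a, records_b), labels, ("tab:blue", "tab:pink")):
        x = [r.achromatic_diff for r in recs]
        y = [r.chromatic_diff for r in recs]
        ax.plot(x, y, "o", ms=3, alpha=0.6, color=color, label=label)
        ax.plot(np.mean(x), np.mean(y), "+", ms=18, mew=2.5, color=color)
    ax.set_xlabel("mean local achromatic difference")
    ax.set_ylabel("mean local chromatic difference")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _analyze_corpus(
    images: list[RasterImage],
    label: str,
    cfg: RunConfig,
    cs_cfg: ColorSpaceConfig,
    out: Path,
    seed: int,
) -> dict:
    dkls = [srgb_to_dkl(img, cs_cfg) for img in images]
    result: dict = {"n_images": len(images)}
    hists_by_plane: dict[str, list[JointHistogram]] = {}

    for plane_name in cfg.planes:
        plane = PLANES[plane_name]
        hists = [compute_joint_histogram(dkl, plane) for dkl in dkls]
        hists_by_plane[plane_name] = hists
        mean_h = mean_histogram(hists)
        histogram_to_csv(mean_h, out / f"mean_hist_{label}_{plane_name}.csv")

        focus = QuadrantSet.of(cfg.focus_quadrants[plane_name])
        rest = QuadrantSet.complement_of(focus)
        focus_curves = [contrast_curve(h, focus) for h in hists]
        rest_curves = [contrast_curve(h, rest) for h in hists]
        # one seed per (corpus, plane, quadrant-set) bootstrap
        focus_band = bootstrap_band(focus_curves, cfg.n_boot, cfg.level, seed=seed)
        rest_band = bootstrap_band(rest_curves, cfg.n_boot, cfg.level, seed=seed + 1)
        levels = focus_curves[0].contrast_values
        frame = _curves_frame(levels, focus_band, rest_band, cfg.sigma)
        frame.to_csv(out / f"curves_{label}_{plane_name}.csv", index=False)
        # per-image unsmoothed densities: every statistic is recomputable
        per_img = pd.DataFrame(
            {"contrast": levels}
            | {f"focus_{i}": c.density for i, c in enumerate(focus_curves)}
            | {f"rest_{i}": c.density for i, c in enumerate(rest_curves)}
        )
        per_img.to_csv(out / f"per_image_curves_{label}_{plane_name}.csv", index=False)

        stat = warm_excess_statistic(focus_curves, rest_curves)
        result[f"excess_{plane_name}"] = stat
        result[f"out_of_range_fraction_{plane_name}"] = mean_h.out_of_range_fraction

        if cfg.write_plots:
            _plot_histogram(mean_h, out / f"mean_hist_{label}_{plane_name}.png",
                            f"{label} {plane_name}")
            chromo = _mean_chromogram(images, dkls, plane)
            chromogram_to_png(chromo, out / f"chromogram_{label}_{plane_name}.png")
            _plot_curves(frame, out / f"curves_{label}_{plane_name}.png",
                         f"{label} {plane_name} {focus.label} vs {rest.label}")
        seed += 2

    result["warm_excess"] = result[f"excess_{cfg.warm_plane}"]
    if cfg.blue_plane in cfg.planes:
        # Q3-vs-rest mirrors the published comparison; the control statistic
        # references only the other non-warm quadrant (Q2), so that a warm
        # saturation effect cannot contaminate the cool-quadrant control.
        result["blue_excess"] = result[f"excess_{cfg.blue_plane}"]
        blue_hists = hists_by_plane[cfg.blue_plane]
        focus = QuadrantSet.of(cfg.focus_quadrants[cfg.blue_plane])
        ref = QuadrantSet.of(*cfg.blue_control_reference)
        result["blue_control"] = warm_excess_statistic(
            [contrast_curve(h, focus) for h in blue_hists],
            [contrast_curve(h, ref) for h in blue_hists],
        )

    records = [image_local_diffs(img, group=label) for img in images]
    records_to_csv(records, out / f"localdiff_{label}.csv")
    corr = correlate_diffs(records)
    result["local_diff_correlation"] = {"n": corr.n, "r": corr.r, "p": corr.p}
    result["_records"] = records
    return result


def run_analysis(cfg: RunConfig) -> AnalysisReport:
    """Execute the full two-corpus comparison; returns the report.

    Writes ``report.json``, per-plane histogram and curve tables, local
    difference records, and (optionally) plots into ``cfg.output_dir``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cs_cfg = (
        ColorSpaceConfig.from_file(cfg.colorspace_file)
        if cfg.colorspace_file
        else ColorSpaceConfig()
    )

    images_a, skipped_a = load_corpus(cfg.corpus_a_dir)
    images_b, skipped_b = load_corpus(cfg.corpus_b_dir)

    seeds = np.random.SeedSequence(cfg.seed).generate_state(2)
    res_a = _analyze_corpus(images_a, cfg.label_a, cfg, cs_cfg, out, int(seeds[0] % 2**31))
    res_b = _analyze_corpus(images_b, cfg.label_b, cfg, cs_cfg, out, int(seeds[1] % 2**31))
    res_a["n_skipped"] = skipped_a
    res_b["n_skipped"] = skipped_b

    records_a = res_a.pop("_records")
    records_b = res_b.pop("_records")
    if cfg.write_plots:
        _plot_scatter(records_a, records_b, (cfg.label_a, cfg.label_b), out / "localdiff_scatter.png")

    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]

    report = AnalysisReport(
        data={
            "config": cfg_dict,
            "config_hash": cfg_hash,
            "version": __version__,
            "corpora": {cfg.label_a: res_a, cfg.label_b: res_b},
            "difference": {
                "warm_excess": res_a["warm_excess"] - res_b["warm_excess"],
                **(
                    {
                        "blue_excess": res_a["blue_excess"] - res_b["blue_excess"],
                        "blue_control": res_a["blue_control"] - res_b["blue_control"],
                    }
                    if "blue_excess" in res_a
                    else {}
                ),
            },
        }
    )
    report.write(out / "report.json")
    return report
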