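"""Synthetic still-life corpora with known chromatic ground truth.

The generator emulates the statistical structure the corpus analysis
assumes: images dominated by two opposing chromatic quadrants (warm
elliptical "fruit" blobs on a cool background), a controllable excess of
radial chromatic contrast for the warm pixels (``warm_saturation_gain``),
and dark-biased luminance.  Pixels are authored directly in DKL
coordinates and mapped to sRGB through the inverse of the configured
color transform, so the ground-truth chromatic contrast of every pixel is
exact by construction rather than estimated; out-of-gamut pixels are
clipped and the clipped fraction reported.

Chromatic texture rotates each pixel's chroma vector by a small
angle (hue-orthogonal jitter), leaving radial contrast untouched;
luminance texture is independent smooth noise.  The two texture channels
therefore control the local chromatic and achromatic difference
statistics independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .colorspace import (
    ColorSpaceConfig,
    DKLImage,
    RasterImage,
    dkl_to_linear,
    linear_to_srgb,
)

__all__ = [
    "StillLifeParams",
    "GroundTruth",
    "generate_still_life",
    "generate_corpus",
    "fixture_images",
    "write_corpus",
    "write_fixtures",
    "CONDITION_GAINS",
]

#: Default warm-saturation gain per corpus condition.  The painting-like
#: condition injects a larger relative chromatic contrast for warm pixels.
CONDITION_GAINS = {"painting-like": 1.5, "photo-like": 1.15}


@dataclass
class StillLifeParams:
    """Parameters of one synthetic still-life image.

    ``warm_saturation_gain`` multiplies the radial chromatic contrast of
    fruit pixels relative to ``base_saturation`` (the background's radial
    contrast, in the scaled DKL units of the [-2, 2] histogram range).
    ``luminance_dark_bias`` is the exact fraction of pixels placed below
    mid-luminance.  Hue intervals are angles in the isoluminant plane and
    must stay within one quadrant.
    """

    width: int = 128
    height: int = 128
    n_fruits: int = 5
    fruit_hue_range: tuple[float, float] = (0.3, 1.25)  # within Q1 (0, pi/2)
    background_hue: float = np.pi + 0.8  # within Q3 (pi, 3*pi/2)
    warm_saturation_gain: float = 1.0
    base_saturation: float = 0.45
    luminance_dark_bias: float = 0.6
    chroma_texture_amp: float = 0.05  # radians of hue-orthogonal jitter
    lum_texture_amp: float = 0.5  # achromatic-axis noise std (axis spans [-2, 2])
    fruit_lum_offset: float = 0.15  # fruit pixels slightly brighter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("image dimensions must be >= 64")
        if self.warm_saturation_gain < 0 or self.base_saturation < 0:
            raise ValueError("saturations must be non-negative")
        if self.chroma_texture_amp < 0 or self.lum_texture_amp < 0:
            raise ValueError("texture amplitudes must be non-negative")
        lo, hi = self.fruit_hue_range
        if not (lo < hi and np.floor(lo / (np.pi / 2)) == np.floor((hi - 1e-12) / (np.pi / 2))):
            raise ValueError("fruit hue range must lie within a single quadrant")
        if not 0.0 <= self.luminance_dark_bias <= 1.0:
            raise ValueError("luminance_dark_bias must be a fraction")


@dataclass
class GroundTruth:
    """What the generator actually put into the image."""

    fruit_mask: np.ndarray
    fruit_mean_contrast: float
    background_mean_contrast: float
    clipped_fraction: float
    params: StillLifeParams = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = int(self.fruit_mask.sum())
        if n == 0 or n == self.fruit_mask.size:
            raise ValueError("fruit mask must be non-empty and not cover the whole image")


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Seeded smooth noise field standardized to zero mean, unit variance."""
    field_ = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    std = field_.std()
    if std == 0:
        return np.zeros(shape)
    return (field_ - field_.mean()) / std


def _fruit_mask(rng: np.random.Generator, h: int, w: int, n_fruits: int) -> np.ndarray:
    """Union of randomly placed, rotated ellipses."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    mask = np.zeros((h, w), dtype=bool)
    scale = min(h, w)
    for _ in range(max(n_fruits, 1)):
        cy = rng.uniform(0.2, 0.8) * h
        cx = rng.uniform(0.2, 0.8) * w
        a = rng.uniform(0.07, 0.16) * scale
        b = rng.uniform(0.07, 0.16) * scale
        phi = rng.uniform(0, np.pi)
        dx = xx - cx
        dy = yy - cy
        xr = dx * np.cos(phi) + dy * np.sin(phi)
        yr = -dx * np.sin(phi) + dy * np.cos(phi)
        mask |= (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    return mask


def generate_still_life(
    params: StillLifeParams,
    cfg: ColorSpaceConfig | None = None,
    quantize_16bit: bool = True,
) -> tuple[RasterImage, GroundTruth]:
    """Render one synthetic still life and its exact ground truth.

    Fruit pixels get radial chromatic contrast ``gain * base_saturation``
    at warm-quadrant hues; background pixels sit at ``base_saturation`` in
    the opposing cool quadrant.  With ``quantize_16bit`` the sRGB output is
    rounded to 16-bit levels so written PNGs round-trip losslessly.
    """
    cfg = cfg or ColorSpaceConfig()
    h, w = params.height, params.width
    rng = np.random.default_rng(params.seed)

    mask = _fruit_mask(rng, h, w, params.n_fruits)
    if not mask.any() or mask.all():
        raise ValueError("degenerate fruit mask; adjust size or fruit count")

    # hue per blob region: label by re-rendering isn't needed — draw one hue
    # field where every fruit pixel gets a hue from the warm interval
    hue = np.full((h, w), params.background_hue)
    hue[mask] = rng.uniform(*params.fruit_hue_range)
    # angular (hue-orthogonal) texture preserves radial contrast exactly
    theta = hue + params.chroma_texture_amp * _smooth_noise(rng, (h, w), min(h, w) / 24)

    radial = np.where(
        mask,
        params.warm_saturation_gain * params.base_saturation,
        params.base_saturation,
    )
    lm = radial * np.cos(theta)
    s = radial * np.sin(theta)

    # luminance: smooth texture plus a fruit brightening, shifted so that
    # exactly the requested fraction of pixels lies below mid-luminance
    ach = params.fruit_lum_offset * mask + params.lum_texture_amp * _smooth_noise(
        rng, (h, w), min(h, w) / 12
    )
    ach -= np.quantile(ach, params.luminance_dark_bias)

    dkl = DKLImage(ach=ach, lm=lm, s=s)
    linear = dkl_to_linear(dkl, cfg)
    clipped = np.any((linear < -1e-9) | (linear > 1.0 + 1e-9), axis=-1)
    clipped_fraction = float(clipped.mean())
    if clipped_fraction >= 1.0:
        raise ValueError("all pixels out of gamut; reduce saturation or luminance range")
    srgb = linear_to_srgb(np.clip(linear, 0.0, 1.0))
    if quantize_16bit:
        srgb = np.round(srgb * 65535.0) / 65535.0

    img = RasterImage(pixels=srgb, source_id=f"synthetic_{params.seed}", bit_depth=16)
    truth = GroundTruth(
        fruit_mask=mask,
        fruit_mean_contrast=params.warm_saturation_gain * params.base_saturation,
        background_mean_contrast=params.base_saturation,
        clipped_fraction=clipped_fraction,
        params=params,
    )
    return img, truth


def generate_corpus(
    n_images: int,
    condition: str = "painting-like",
    seed: int = 0,
    base_params: StillLifeParams | None = None,
    warm_saturation_gain: float | None = None,
    cfg: ColorSpaceConfig | None = None,
) -> list[tuple[RasterImage, GroundTruth]]:
    """Seeded draw of per-image parameters for one corpus condition.

    Conditions share all parameters except the warm-saturation gain
    (painting-like 1.5, photo-like 1.15 by default); ``warm_saturation_gain``
    overrides the condition's gain.  Per-image seeds and fruit counts are
    derived from the corpus seed.
    """
    if n_images < 2:
        raise ValueError("a corpus needs at least 2 images")
    if warm_saturation_gain is None:
        if condition not in CONDITION_GAINS:
            raise ValueError(
                f"unknown condition {condition!r}; pass warm_saturation_gain explicitly"
            )
        warm_saturation_gain = CONDITION_GAINS[condition]
    base = base_params or StillLifeParams()
    corpus_rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        params = replace(
            base,
            warm_saturation_gain=warm_saturation_gain,
            n_fruits=int(corpus_rng.integers(3, 8)),
            seed=int(corpus_rng.integers(0, 2**31 - 1)),
        )
        img, truth = generate_still_life(params, cfg=cfg)
        img.source_id = f"{condition}_{i:03d}"
        out.append((img, truth))
    return out


# -- deterministic fixture images -------------------------------------------


def fixture_images() -> dict[str, RasterImage]:
    """Named deterministic test images used across the pipeline's examples.

    Values are exact floats (e.g. the gray fixture is exactly 0.5);
    :func:`write_fixtures` quantizes to 16-bit TIFF.
    """
    fixtures: dict[str, RasterImage] = {}

    fixtures["gray"] = RasterImage(np.full((16, 16, 3), 0.5), "gray")

    ramp = np.tile(np.linspace(0.0, 1.0, 64)[None, :, None], (16, 1, 3))
    fixtures["achromatic_ramp"] = RasterImage(ramp, "achromatic_ramp")

    # exactly 30 pixels of a warm color, 70 of a cool color (10x10)
    warm = np.array([0.85, 0.35, 0.20])
    cool = np.array([0.25, 0.40, 0.75])
    px = np.tile(cool, (100, 1))
    px[:30] = warm
    fixtures["two_color_30_70"] = RasterImage(px.reshape(10, 10, 3), "two_color_30_70")

    step = np.full((16, 16, 3), 0.3)
    step[:, 8:] = 0.7  # achromatic step: chromaticity constant, L steps
    fixtures["luminance_step"] = RasterImage(step, "luminance_step")

    # two chromatic colors with exactly equal relative luminance Y
    a_lin = np.array([0.30, 0.15, 0.10])
    y_row = np.array([0.2126729, 0.7151522, 0.0721750])
    b_lin = np.array([0.0, 0.15, 0.35])
    b_lin[0] = (y_row @ a_lin - y_row[1] * b_lin[1] - y_row[2] * b_lin[2]) / y_row[0]
    cstep = np.empty((16, 16, 3))
    cstep[:, :8] = linear_to_srgb(a_lin)
    cstep[:, 8:] = linear_to_srgb(b_lin)
    fixtures["chromaticity_step"] = RasterImage(cstep, "chromaticity_step")

    t = np.linspace(0.0, 1.0, 4)
    r, g, b = np.meshgrid(t, t, t, indexing="ij")
    cube = np.stack([r.ravel(), g.ravel(), b.ravel()], axis=1).reshape(8, 8, 3)
    fixtures["rgb_cube_grid"] = RasterImage(cube, "rgb_cube_grid")

    return fixtures


# -- writers -----------------------------------------------------------------


def _write_tiff16(img: RasterImage, path: Path) -> None:
    # 16-bit RGB TIFF: lossless for quantized synthetic images
    iio.imwrite(path, np.round(img.pixels * 65535.0).astype(np.uint16))


def write_corpus(
    out_dir: str | Path,
    n_images: int,
    condition: str = "painting-like",
    seed: int = 0,
    base_params: StillLifeParams | None = None,
    cfg: ColorSpaceConfig | None = None,
) -> pd.DataFrame:
    """Write a corpus as 16-bit TIFFs plus mask PNGs and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(exist_ok=True)
    rows = []
    for img, truth in generate_corpus(
        n_images, condition=condition, seed=seed, base_params=base_params, cfg=cfg
    ):
        _write_tiff16(img, out_dir / f"{img.source_id}.tiff")
        iio.imwrite(
            mask_dir / f"{img.source_id}_mask.png",
            (truth.fruit_mask * 255).astype(np.uint8),
        )
        rows.append(
            {
                "source_id": img.source_id,
                "condition": condition,
                "seed": truth.params.seed,
                "warm_saturation_gain": truth.params.warm_saturation_gain,
                "clipped_fraction": truth.clipped_fraction,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Write all fixture images as 16-bit TIFFs; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, img in fixture_images().items():
        path = out_dir / f"{name}.tiff"
        _write_tiff16(img, path)
        paths.append(path)
    return paths
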