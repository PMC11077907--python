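"""Color-space conversions for corpus color statistics.

Images enter the pipeline as sRGB-encoded rasters and are analyzed in a
cone-opponent (DKL) representation: one achromatic axis and two chromatic
axes (an L-vs-M "teal–cherry" axis and an S-cone "violet–lime" axis),
expressed as cone contrast relative to a fixed adapting background
(mid-gray by default).  A second, independent path converts images to a
CIELUV-style (L, u', v') representation for local chromatic/achromatic
difference statistics.

The RGB→XYZ→LMS matrices, the adapting background, and the per-axis scale
and sign all live in :class:`ColorSpaceConfig` and can be overridden from a
flat key–value config file; the defaults use the IEC sRGB primaries with
D65 white and the Hunt–Pointer–Estévez cone fundamentals (D65-normalized),
with each chromatic axis scaled so the most saturated RGB-cube corner maps
to magnitude 2.0 (the histogram range used downstream is [-2, 2]).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

logger = logging.getLogger("chromacontrast")

__all__ = [
    "RasterImage",
    "ColorSpaceConfig",
    "DKLImage",
    "LUVImage",
    "srgb_to_linear",
    "linear_to_srgb",
    "linear_to_dkl",
    "dkl_to_linear",
    "srgb_to_dkl",
    "srgb_to_luv",
    "rgb_cube_projection",
    "read_image",
]

# IEC 61966-2-1 sRGB primaries, D65 white.
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# Hunt–Pointer–Estévez cone fundamentals, normalized to D65.
XYZ_TO_LMS_HPE = np.array(
    [
        [0.40024, 0.70760, -0.08081],
        [-0.22630, 1.16532, 0.04570],
        [0.0, 0.0, 0.91822],
    ]
)

#: (u', v') of D65, used for the 0/0 chromaticity convention at black.
D65_WHITE_UV = (0.19783982, 0.46833631)


@dataclass
class RasterImage:
    """An sRGB-encoded image with values scaled to [0, 1].

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` float array of sRGB-encoded values in ``[0, 1]``.
    source_id
        Identifier for provenance (file stem, generator tag, ...).
    bit_depth
        Bits per channel of the original encoding (8 or 16 for files;
        synthetic images default to 16).
    """

    pixels: np.ndarray
    source_id: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(f"image too small: {px.shape[0]}x{px.shape[1]} (need >= 3x3)")
        if not np.isfinite(px).all():
            raise ValueError("non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"pixel values outside [0, 1]: min={px.min():.4g}, max={px.max():.4g}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class DKLImage:
    """Per-pixel cone-opponent coordinates (lights convention axis names).

    ``ach`` is the achromatic L/M/S axis, ``lm`` the chromatic teal–cherry
    L/M axis (positive toward cherry/red), ``s`` the chromatic violet–lime
    S axis (positive toward lime, so the warm red–orange–yellow colors fall
    in the (+lm, +s) quadrant of the isoluminant plane).
    """

    ach: np.ndarray
    lm: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        if not (self.ach.shape == self.lm.shape == self.s.shape):
            raise ValueError("DKL planes must share one H x W shape")
        for name in ("ach", "lm", "s"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"non-finite values in DKL plane {name!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ach.shape

    def axis(self, name: str) -> np.ndarray:
        """Return one coordinate plane by axis name ('ach', 'lm' or 's')."""
        if name not in ("ach", "lm", "s"):
            raise KeyError(f"unknown DKL axis {name!r}")
        return getattr(self, name)


@dataclass
class LUVImage:
    """(L, u', v') image: a luminance channel plus CIE 1976 UCS chromaticity."""

    L: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        if not (self.L.shape == self.u.shape == self.v.shape):
            raise ValueError("LUV planes must share one H x W shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("non-finite chromaticity values")
        if (self.L < 0).any():
            raise ValueError("negative luminance")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape


def srgb_to_linear(values: np.ndarray | RasterImage) -> np.ndarray:
    """Decode sRGB-encoded values in [0, 1] to linear light (EOTF)."""
    if isinstance(values, RasterImage):
        values = values.pixels
    v = np.asarray(values, dtype=np.float64)
    if v.size and (v.min() < 0.0 or v.max() > 1.0):
        raise ValueError("sRGB values must lie in [0, 1]")
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(values: np.ndarray) -> np.ndarray:
    """Encode linear-light values in [0, 1] with the sRGB OETF."""
    v = np.asarray(values, dtype=np.float64)
    if v.size and (v.min() < 0.0 or v.max() > 1.0):
        raise ValueError("linear values must lie in [0, 1]")
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def _opponent_matrix(background_lms: np.ndarray) -> np.ndarray:
    """Rows map cone increments (ΔL, ΔM, ΔS) to raw opponent contrasts.

    ach = (ΔL+ΔM)/(L0+M0);  lm = ΔL/L0 − ΔM/M0;  s = ΔS/S0 − (ΔL+ΔM)/(L0+M0).
    """
    L0, M0, S0 = background_lms
    return np.array(
        [
            [1.0 / (L0 + M0), 1.0 / (L0 + M0), 0.0],
            [1.0 / L0, -1.0 / M0, 0.0],
            [-1.0 / (L0 + M0), -1.0 / (L0 + M0), 1.0 / S0],
        ]
    )


@dataclass
class ColorSpaceConfig:
    """Matrices, adapting background and axis calibration for the DKL transform.

    ``axis_scale`` maps raw opponent contrasts onto the [-2, 2] histogram
    range; ``axis_sign`` fixes polarity (defaults: +lm toward cherry/red,
    +s toward lime).  ``background_rgb`` is the adapting background in
    *linear* RGB; it maps to the DKL origin.
    """

    rgb_to_xyz: np.ndarray = field(default_factory=lambda: SRGB_TO_XYZ.copy())
    xyz_to_lms: np.ndarray = field(default_factory=lambda: XYZ_TO_LMS_HPE.copy())
    background_rgb: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5, 0.5]))
    axis_scale: np.ndarray | None = None
    axis_sign: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, -1.0]))

    def __post_init__(self) -> None:
        self.rgb_to_xyz = np.asarray(self.rgb_to_xyz, dtype=np.float64).reshape(3, 3)
        self.xyz_to_lms = np.asarray(self.xyz_to_lms, dtype=np.float64).reshape(3, 3)
        self.background_rgb = np.asarray(self.background_rgb, dtype=np.float64).reshape(3)
        self.axis_sign = np.asarray(self.axis_sign, dtype=np.float64).reshape(3)
        for name, mat in (("rgb_to_xyz", self.rgb_to_xyz), ("xyz_to_lms", self.xyz_to_lms)):
            if abs(np.linalg.det(mat)) < 1e-12:
                raise ValueError(f"{name} matrix is singular")
        if not np.all(np.isin(self.axis_sign, (-1.0, 1.0))):
            raise ValueError("axis_sign entries must be +1 or -1")
        self.rgb_to_lms = self.xyz_to_lms @ self.rgb_to_xyz
        self.background_lms = self.rgb_to_lms @ self.background_rgb
        if (self.background_lms <= 0).any():
            raise ValueError("background cone excitations must be strictly positive")
        if self.axis_scale is None:
            self.axis_scale = self._calibrate_axis_scale()
        self.axis_scale = np.asarray(self.axis_scale, dtype=np.float64).reshape(3)
        if (self.axis_scale <= 0).any():
            raise ValueError("axis_scale must be strictly positive")
        # Affine map: dkl = A @ rgb_linear + b  (cone contrast is linear in LMS,
        # hence in linear RGB, for a fixed background).
        opp = _opponent_matrix(self.background_lms)
        diag = np.diag(self.axis_sign * self.axis_scale)
        self.dkl_matrix = diag @ opp @ self.rgb_to_lms
        self.dkl_offset = -diag @ opp @ self.background_lms

    def _calibrate_axis_scale(self) -> np.ndarray:
        """Gamut calibration: the most extreme RGB-cube corner on each axis → |2.0|.

        The transform is affine in linear RGB, so extrema over the cube are
        attained at its 8 corners.
        """
        opp = _opponent_matrix(self.background_lms)
        corners = np.array(
            [[r, g, b] for r in (0.0, 1.0) for g in (0.0, 1.0) for b in (0.0, 1.0)]
        )
        raw = (opp @ (self.rgb_to_lms @ corners.T - self.background_lms[:, None])).T
        return 2.0 / np.abs(raw).max(axis=0)

    # -- flat key-value config file ------------------------------------------

    def to_file(self, path: str | Path) -> None:
        data = {
            "rgb_to_xyz": [float(x) for x in self.rgb_to_xyz.ravel()],
            "xyz_to_lms": [float(x) for x in self.xyz_to_lms.ravel()],
            "background_rgb": [float(x) for x in self.background_rgb],
            "axis_scale": [float(x) for x in self.axis_scale],
            "axis_sign": [float(x) for x in self.axis_sign],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "ColorSpaceConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "rgb_to_xyz" in data:
            kwargs["rgb_to_xyz"] = np.asarray(data["rgb_to_xyz"], float).reshape(3, 3)
        if "xyz_to_lms" in data:
            kwargs["xyz_to_lms"] = np.asarray(data["xyz_to_lms"], float).reshape(3, 3)
        if "background_rgb" in data:
            kwargs["background_rgb"] = np.asarray(data["background_rgb"], float)
        if "axis_scale" in data:
            kwargs["axis_scale"] = np.asarray(data["axis_scale"], float)
        if "axis_sign" in data:
            kwargs["axis_sign"] = np.asarray(data["axis_sign"], float)
        return cls(**kwargs)


def linear_to_dkl(linear: np.ndarray, cfg: ColorSpaceConfig) -> DKLImage:
    """Map linear RGB pixels to scaled cone-opponent coordinates.

    The adapting background maps to the origin on all three axes.
    """
    lin = np.asarray(linear, dtype=np.float64)
    if lin.ndim != 3 or lin.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) linear RGB, got {lin.shape}")
    flat = lin.reshape(-1, 3)
    dkl = flat @ cfg.dkl_matrix.T + cfg.dkl_offset
    dkl = dkl.reshape(lin.shape)
    return DKLImage(ach=dkl[..., 0], lm=dkl[..., 1], s=dkl[..., 2])


def dkl_to_linear(dkl: DKLImage, cfg: ColorSpaceConfig) -> np.ndarray:
    """Invert the affine DKL map back to linear RGB (no gamut clipping)."""
    coords = np.stack([dkl.ach, dkl.lm, dkl.s], axis=-1)
    inv = np.linalg.inv(cfg.dkl_matrix)
    flat = (coords.reshape(-1, 3) - cfg.dkl_offset) @ inv.T
    return flat.reshape(coords.shape)


def srgb_to_dkl(img: RasterImage, cfg: ColorSpaceConfig) -> DKLImage:
    """Full chain sRGB-encoded image → linear RGB → DKL."""
    return linear_to_dkl(srgb_to_linear(img.pixels), cfg)


def srgb_to_luv(img: RasterImage | np.ndarray, l_mode: str = "Y") -> LUVImage:
    """Convert an sRGB image to (L, u', v').

    u' = 4X/(X+15Y+3Z), v' = 9Y/(X+15Y+3Z); pixels with X=Y=Z=0 take the
    D65 white-point chromaticity to avoid 0/0.  ``l_mode="Y"`` (default)
    uses relative luminance Y in [0, 1] as the L channel; ``l_mode="Lstar"``
    uses CIE L* (0–100, D65 white).
    """
    pixels = img.pixels if isinstance(img, RasterImage) else np.asarray(img, float)
    lin = srgb_to_linear(pixels)
    xyz = lin.reshape(-1, 3) @ SRGB_TO_XYZ.T
    X, Y, Z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    denom = X + 15.0 * Y + 3.0 * Z
    zero = denom <= 0.0
    safe = np.where(zero, 1.0, denom)
    u = np.where(zero, D65_WHITE_UV[0], 4.0 * X / safe)
    v = np.where(zero, D65_WHITE_UV[1], 9.0 * Y / safe)
    if l_mode == "Y":
        L = Y
    elif l_mode == "Lstar":
        yr = np.clip(Y, 0.0, None)  # white Y == 1 for sRGB
        L = np.where(yr > (6 / 29) ** 3, 116.0 * np.cbrt(yr) - 16.0, (29 / 3) ** 3 * yr)
    else:
        raise ValueError(f"unknown l_mode {l_mode!r}")
    shape = pixels.shape[:2]
    return LUVImage(L=L.reshape(shape), u=u.reshape(shape), v=v.reshape(shape))


def rgb_cube_projection(cfg: ColorSpaceConfig, samples_per_edge: int = 16) -> np.ndarray:
    """DKL coordinates of a regular grid over the linear RGB cube.

    Returns an ``(samples_per_edge**3, 3)`` array of (ach, lm, s) points —
    the display gamut as seen in each DKL plane; used to draw gamut
    outlines and to check the axis calibration.
    """
    if samples_per_edge < 2:
        raise ValueError("samples_per_edge must be >= 2")
    t = np.linspace(0.0, 1.0, samples_per_edge)
    r, g, b = np.meshgrid(t, t, t, indexing="ij")
    grid = np.stack([r.ravel(), g.ravel(), b.ravel()], axis=1)
    return grid @ cfg.dkl_matrix.T + cfg.dkl_offset


def read_image(path: str | Path, assume_linear: bool = False) -> RasterImage:
    """Read a PNG or TIFF (8- or 16-bit) as an sRGB-encoded RasterImage.

    Alpha channels are dropped; grayscale images are replicated to three
    channels with a warning.  Integer data are divided by ``2**bits - 1``.
    If ``assume_linear`` the stored values are treated as linear light and
    re-encoded to sRGB so downstream code sees one convention.
    """
    path = Path(path)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: grayscale image replicated to 3 channels")
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: unsupported image shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    elif arr.shape[2] != 3:
        raise ValueError(f"{path.name}: unsupported channel count {arr.shape[2]}")
    if np.issubdtype(arr.dtype, np.integer):
        bits = arr.dtype.itemsize * 8
        px = arr.astype(np.float64) / (2**bits - 1)
    else:
        bits = 16
        px = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if assume_linear:
        px = linear_to_srgb(px)
    return RasterImage(pixels=px, source_id=path.stem, bit_depth=bits)
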