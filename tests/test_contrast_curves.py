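"""Contrast-level enumeration, quadrant curves, smoothing and the excess statistic."""

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromacontrast as cc
from chromacontrast.contrast_curves import (
    BLUE,
    REST,
    WARM,
    QuadrantSet,
    contrast_curve,
    contrast_level_index,
    curve_difference,
    enumerate_contrast_levels,
    round_contrast,
    smooth_curve,
    warm_excess_statistic,
)
from chromacontrast.joint_histograms import ISOLUMINANT, JointHistogram, bin_edges, compute_joint_histogram

from .conftest import small_params


def decimal_round4(x: float) -> float:
    """Independent 4-decimal rounding oracle (half away from zero)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def random_histogram(rng, n_nonzero=60) -> JointHistogram:
    counts = np.zeros((128, 128))
    ix = rng.integers(0, 128, n_nonzero)
    iy = rng.integers(0, 128, n_nonzero)
    counts[ix, iy] = rng.uniform(0, 1, n_nonzero)
    counts /= counts.sum()
    e = bin_edges()
    return JointHistogram(ISOLUMINANT, counts, e, e.copy(), n_pixels_total=1000)


class TestLevelEnumeration:
    def test_default_grid_has_1464_levels(self):
        assert enumerate_contrast_levels().size == 1464

    def test_matches_decimal_brute_force(self):
        centers = -2 + (np.arange(128) + 0.5) * (4 / 128)
        seen = set()
        for cx in centers:
            for cy in centers:
                seen.add(decimal_round4(float(np.hypot(cx, cy))))
        assert np.array_equal(enumerate_contrast_levels(), np.array(sorted(seen)))

    def test_two_by_two_grid_collapses_to_one_level(self):
        levels = enumerate_contrast_levels(2, (-2.0, 2.0))
        assert levels.size == 1
        assert levels[0] == pytest.approx(round_contrast(np.sqrt(2.0)))

    def test_level_index_is_consistent(self):
        levels = enumerate_contrast_levels()
        index = contrast_level_index()
        centers = -2 + (np.arange(128) + 0.5) * (4 / 128)
        cx, cy = np.meshgrid(centers, centers, indexing="ij")
        assert np.array_equal(levels[index], round_contrast(np.hypot(cx, cy)))


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=4.0, allow_nan=False))
def test_round_contrast_matches_decimal_oracle(value):
    expected = float(Decimal(repr(value)).quantize(Decimal("0.0001"), ROUND_HALF_UP))
    assert round_contrast(value) == pytest.approx(expected, abs=5e-13)


class TestQuadrantSet:
    def test_sizes_on_default_grid(self):
        assert WARM.n_bins() == 64 * 64
        assert REST.n_bins() == 3 * 64 * 64
        assert QuadrantSet.of(*"Q1 Q2 Q3 Q4".split()).n_bins() == 128 * 128

    def test_no_center_on_axis(self):
        # membership must be total: masks of complementary sets partition the grid
        assert (WARM.mask() ^ REST.mask()).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            QuadrantSet(frozenset())
        with pytest.raises(ValueError):
            QuadrantSet.of("Q5")


class TestContrastCurve:
    def test_matches_brute_force_grouping(self, rng):
        hist = random_histogram(rng)
        centers = -2 + (np.arange(128) + 0.5) * (4 / 128)
        for quads in (WARM, REST, BLUE):
            curve = contrast_curve(hist, quads)
            groups: dict[float, float] = {}
            for ix, iy in zip(*np.nonzero(hist.counts)):
                x, y = centers[ix], centers[iy]
                in_set = False
                for q in quads.included:
                    sx, sy = {"Q1": (1, 1), "Q2": (-1, 1), "Q3": (-1, -1), "Q4": (1, -1)}[q]
                    in_set |= (x * sx > 0) and (y * sy > 0)
                if in_set:
                    level = decimal_round4(float(np.hypot(x, y)))
                    groups[level] = groups.get(level, 0.0) + hist.counts[ix, iy]
            expected = np.zeros_like(curve.density)
            for level, mass in groups.items():
                expected[np.searchsorted(curve.contrast_values, level)] = mass
            assert np.allclose(curve.density * quads.n_bins(), expected, atol=1e-15)

    def test_uniform_histogram_gives_equal_normalized_curves(self):
        e = bin_edges()
        hist = JointHistogram(
            ISOLUMINANT, np.full((128, 128), 1 / 16384), e, e.copy(), n_pixels_total=16384
        )
        q1 = contrast_curve(hist, WARM)
        q234 = contrast_curve(hist, REST)
        assert np.allclose(q1.density, q234.density, atol=1e-15)

    def test_origin_mass_lands_on_smallest_level(self):
        counts = np.zeros((128, 128))
        counts[63:65, 63:65] = 0.25  # the four bins nearest the origin
        e = bin_edges()
        hist = JointHistogram(ISOLUMINANT, counts, e, e.copy(), n_pixels_total=4)
        curve = contrast_curve(hist, QuadrantSet.of(*"Q1 Q2 Q3 Q4".split()))
        nz = np.nonzero(curve.density)[0]
        assert np.array_equal(nz, [0])

    def test_partition_identity(self, rng):
        """Count-weighted Q1 + Q234 recombine to the all-quadrant profile."""
        hist = random_histogram(rng)
        q1 = contrast_curve(hist, WARM)
        rest = contrast_curve(hist, REST)
        full = contrast_curve(hist, QuadrantSet.of(*"Q1 Q2 Q3 Q4".split()))
        recombined = q1.density * WARM.n_bins() + rest.density * REST.n_bins()
        assert np.allclose(recombined, full.density * 16384, atol=1e-15)

    def test_rotation_maps_q1_curve_to_q2_curve(self, rng):
        hist = random_histogram(rng)
        rotated = JointHistogram(
            ISOLUMINANT,
            np.rot90(hist.counts),
            hist.bin_edges_x,
            hist.bin_edges_y,
            n_pixels_total=hist.n_pixels_total,
        )
        q1 = contrast_curve(hist, WARM)
        q2_rot = contrast_curve(rotated, QuadrantSet.of("Q2"))
        assert np.array_equal(q1.density, q2_rot.density)


class TestSmoothing:
    def test_constant_curve_unchanged(self):
        levels = enumerate_contrast_levels()
        curve = cc.ContrastCurve(levels, np.full(levels.size, 0.3), WARM)
        smoothed = smooth_curve(curve, sigma=10)
        assert np.abs(smoothed.density - 0.3).max() < 1e-9

    def test_impulse_becomes_discrete_gaussian(self):
        """Mid-curve unit impulse smooths to the truncated normalized kernel."""
        levels = enumerate_contrast_levels()
        density = np.zeros(levels.size)
        mid = levels.size // 2
        density[mid] = 1.0
        smoothed = smooth_curve(cc.ContrastCurve(levels, density, WARM), sigma=10)
        radius = int(4 * 10 + 0.5)
        offsets = np.arange(-radius, radius + 1)
        kernel = np.exp(-(offsets**2) / (2 * 10.0**2))
        kernel /= kernel.sum()
        expected = np.zeros(levels.size)
        expected[mid - radius : mid + radius + 1] = kernel
        assert np.abs(smoothed.density - expected).max() < 1e-12

    def test_mass_preserved_for_interior_support(self, rng):
        levels = enumerate_contrast_levels()
        density = np.zeros(levels.size)
        density[200:900] = rng.uniform(0, 1, 700)
        curve = cc.ContrastCurve(levels, density, WARM)
        smoothed = smooth_curve(curve, sigma=10)
        assert smoothed.density.sum() == pytest.approx(density.sum(), abs=1e-9)

    def test_invalid_smoothing_rejected(self):
        levels = enumerate_contrast_levels()
        curve = cc.ContrastCurve(levels, np.zeros(levels.size), WARM)
        with pytest.raises(ValueError):
            smooth_curve(curve, sigma=0)
        with pytest.raises(ValueError):
            smooth_curve(smooth_curve(curve, 10), 10)


class TestDifferenceAndStatistic:
    def test_self_difference_is_zero_and_antisymmetric(self, rng):
        hist = random_histogram(rng)
        a = contrast_curve(hist, WARM)
        b = contrast_curve(hist, REST)
        assert np.all(curve_difference(a, a).delta == 0)
        assert np.array_equal(curve_difference(a, b).delta, -curve_difference(b, a).delta)

    def test_mismatched_grids_rejected(self, rng):
        hist = random_histogram(rng)
        a = contrast_curve(hist, WARM)
        small_levels = enumerate_contrast_levels(2, (-2.0, 2.0))
        b = cc.ContrastCurve(small_levels, np.zeros(1), WARM)
        with pytest.raises(ValueError):
            curve_difference(a, b)
        with pytest.raises(ValueError):
            curve_difference(a, smooth_curve(contrast_curve(hist, REST), 10))

    def test_identical_profiles_give_zero_statistic(self, rng):
        hist = random_histogram(rng)
        curves = [contrast_curve(hist, WARM)] * 3
        assert warm_excess_statistic(curves, curves) == 0.0

    def test_statistic_monotone_in_warm_gain(self, cs_cfg):
        """The excess statistic must recover an injected saturation gain.

        Over gains {1.0, 1.25, 1.5, 2.0} and 50 seeded small corpora, at
        least 95% of consecutive-gain comparisons must be non-decreasing.
        """
        gains = [1.0, 1.25, 1.5, 2.0]
        concordant = total = 0
        for seed in range(50):
            stats = []
            for g in gains:
                q_curves, r_curves = [], []
                for img, _ in cc.generate_corpus(
                    4, seed=seed * 997 + 1, base_params=small_params(),
                    warm_saturation_gain=g, cfg=cs_cfg,
                ):
                    dkl = cc.srgb_to_dkl(img, cs_cfg)
                    hist = compute_joint_histogram(dkl, ISOLUMINANT)
                    q_curves.append(contrast_curve(hist, WARM))
                    r_curves.append(contrast_curve(hist, REST))
                stats.append(warm_excess_statistic(q_curves, r_curves))
            for lo, hi in zip(stats, stats[1:]):
                concordant += hi >= lo
                total += 1
        assert concordant / total >= 0.95
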