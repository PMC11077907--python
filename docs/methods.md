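# Methods

This note documents the models, conventions, and numerical choices behind
`chromacontrast`, and what its synthetic-data tests do and do not establish
about real image corpora.

## The cone-opponent (DKL) representation

Pixels are analyzed in a cone-opponent space with one achromatic and two
chromatic axes, named in the lights convention: *L/M/S* (achromatic),
*L/M* (teal–cherry), *S* (violet–lime).  The exact transform behind such an
analysis is rarely published in full; this package fixes a standard,
documented chain and makes every element overridable through
`ColorSpaceConfig`:

* **sRGB decoding.**  The IEC piecewise electro-optical transfer function.
* **RGB → XYZ.**  IEC sRGB primaries with D65 white.
* **XYZ → LMS.**  Hunt–Pointer–Estévez cone fundamentals, D65-normalized.
* **Opponent contrasts.**  With background cone excitations (L₀, M₀, S₀)
  (mid-gray, linear RGB 0.5, by default) and increments ΔL, ΔM, ΔS:

      ach = (ΔL + ΔM) / (L₀ + M₀)
      lm  = ΔL/L₀ − ΔM/M₀
      s   = ΔS/S₀ − (ΔL + ΔM)/(L₀ + M₀)

  Cone contrast relative to a fixed background is linear in LMS and hence
  affine in linear RGB; the whole transform is a single affine map whose
  extremes over the RGB cube occur at its corners.
* **Axis calibration.**  Each axis is scaled so the most extreme RGB-cube
  corner reaches magnitude 2.0 (`axis_scale`), which guarantees that no
  in-gamut pixel falls outside the [−2, 2] histogram range.  Polarity
  (`axis_sign`) defaults to +lm toward cherry/red and +s toward lime.  The
  lime-positive choice for S follows from the quadrant semantics of the
  analysis: the warm quadrant Q1 = (+lm, +s) must contain red, orange *and*
  yellow, and yellow is S-cone-poor; with a violet-positive S axis it would
  fall in Q4.  Under this convention blue lands in Q3, as the blue-quadrant
  control analysis expects.

The comparative conclusions of the analysis (corpus A vs corpus B under one
fixed transform) are insensitive to the precise fundamentals; the config
file exists so users can match a different laboratory convention.

## Histograms and curves

* **Binning.** 128 equal-width bins per axis on [−2, 2]; bins are half-open
  with the last closed.  Pixels outside the range are excluded from the grid
  but counted, so a normalized histogram satisfies
  `sum + out_of_range_fraction = 1` exactly; with the gamut-calibrated
  scaling the out-of-range set is empty for in-gamut input.
* **Contrast levels.** Bin "location" is the bin center.  The chromatic
  contrast of a bin is the Euclidean distance of its center to the origin,
  rounded to four decimal places with half away from zero (MATLAB-style
  `round(x, 4)`; identical to 4 significant digits for values ≥ 1, and the
  grid diagonal is 2√2 < 10).  The default grid yields exactly **1,464**
  unique levels — this count is pinned in the test suite against a
  brute-force enumeration with an independent `decimal`-based rounding.
  Rounding the *significand* to 4 digits instead yields 1,293 levels and is
  therefore not what this analysis means by the operation.
* **Quadrants.** Membership is by strict bin-center sign; centers are odd
  multiples of 1/64, so none lies on an axis and membership is total.
  Per-level sums are divided by the quadrant subset's bin count, making Q1
  (4,096 bins) comparable with Q2+Q3+Q4 (12,288 bins).
* **Smoothing.** 1-D Gaussian along the level index, σ = 10 samples,
  truncated at 4σ, renormalized to unit sum, reflecting boundary (preserves
  mass near zero contrast, where most image mass concentrates).  Order of
  operations: bin → normalize per quadrant → (average across images) →
  smooth last.  Averaging and the bootstrap operate on unsmoothed per-image
  curves; means and band bounds are smoothed identically for display only.

## The warm-excess statistic

A single number summarizing "the warm quadrant's curve sits further out
than the rest":

    W = Σ_c  c · ( d_Q1(c) − d_rest(c) )

the first moment over contrast levels of the unsmoothed mean difference
curve; equivalently the difference in mass-weighted mean contrast per grid
bin.  The naive alternative — the trapezoid area between the curves over the
contrast axis — is *not* used: the unique contrast levels are unevenly
spaced (dense at large radius, sparse near the origin), and the spacing
weight almost exactly cancels a radial shift of mass, making the area
insensitive — and not even monotone — in the very effect the statistic must
detect.  The first moment is monotone in an injected saturation gain
(verified as a test property) and zero when the two quadrant profiles
coincide.

## The blue-quadrant control

A preference-based explanation of a warm effect predicts a similar effect
for blue.  The conventional form of this control compares the blue quadrant Q3
against the three other quadrants of the S-vs-achromatic plane; the package
reports that statistic (`blue_excess`).  For hypothesis testing, however,
that reference is contaminated: the warm pixels whose saturation is under
test have positive S-plane coordinates and sit inside the reference set, so
a genuine warm effect mechanically depresses the blue-vs-rest statistic.
The package therefore also reports `blue_control`, which references only
Q2 — the other non-warm quadrant of that plane — and this is the quantity
used for the specificity check: under the synthetic generator it is exactly
null when only warm saturation is manipulated, while the contaminated
version is not.

## Bootstrap bands

Nonparametric percentile bootstrap of the corpus-mean curve: draw N
per-image curves with replacement (N = corpus size), average, repeat 1,000
times; at each contrast level the band is the 25th and 975th sorted values
(1-based ranks k and n−k with k = ⌊n(1−level)/2⌋).  "Sorting the curves" is
interpreted pointwise per level — the only interpretation that defines an
envelope, since whole curves admit no canonical total order.  Unequal corpus
sizes are bootstrapped at their own N; nothing is subsampled to equalize.
Resampling indices are drawn once per replicate from a single seeded
generator, so bands are bit-identical across runs.

Coverage: for corpora of i.i.d. Gaussian curves the 95% band contains the
true mean at ≈95% of levels.  The test suite checks this at N = 200 curves
per corpus, where the percentile method's small-sample narrowness
(plug-in variance, z-vs-t) is negligible; at small N (≈25) percentile bands
undercover by roughly a percentage point, a known property of the method,
not an implementation artifact.

## Local chromatic and achromatic differences

Images are center-cropped to a square (offsets floored), resized to
256 × 256 with bicubic interpolation (anti-aliased when downscaling,
clipped back to [0, 1]), and converted to (L, u′, v′) with
u′ = 4X/(X+15Y+3Z), v′ = 9Y/(X+15Y+3Z); black pixels take the D65
white-point chromaticity to avoid 0/0.  The **L channel is relative
luminance Y in [0, 1]** by default — the luminance–chromaticity triple the
named conversion chain produces; CIE L* is available via `l_mode="Lstar"`
since the correlation analysis is only approximately invariant to this
choice.  Per interior pixel (the 1-pixel border has no full 8-neighborhood
and is excluded; no padding), the chromatic difference is the mean Euclidean
distance to the 8 neighbors in (u′, v′) and the achromatic difference the
mean |ΔL|; per-image statistics are the interior means.  Corpus-level
association is Pearson's r with the two-sided t-approximation p-value
(a one-sided alternative can be requested explicitly).

## Synthetic still lifes

The generator emulates the statistical structure the analysis assumes, not
the appearance of paintings: `n_fruits` random ellipses with hues drawn
from a warm-quadrant interval (default 0.3–1.25 rad) on a cool-quadrant
background (hue π + 0.8); background radial chromatic contrast
`base_saturation` (0.45 in scaled DKL units), fruit contrast multiplied by
`warm_saturation_gain` (painting-like 1.5, photo-like 1.15); luminance is
smooth seeded noise (std 0.5 on the scaled achromatic axis, matching the
broad, dark-biased luminance distributions of real corpora) shifted so that
exactly `luminance_dark_bias` (0.6) of pixels lie below mid-luminance.
Chromatic texture rotates each pixel's chroma vector (default 0.05 rad,
smooth field), which leaves radial contrast untouched — so ground-truth
contrasts are exact by construction — and is independent of the luminance
texture, giving separate control of the two local-difference channels.
Pixels are authored in DKL and mapped through the inverse of the configured
affine transform; out-of-gamut pixels are clipped and the clipped fraction
reported (< 5% at defaults, typically < 0.5%).

What passing synthetic tests show: every pipeline stage is numerically
correct, the statistic recovers a known injected effect at realistic noise,
and the control is specific.  What they do not show: anything about real
paintings or photographs — real corpora have textured objects, mixed hues,
shading, and reproduction biases the generator deliberately omits.

## Problem sizes and numerical conventions

* Simulation tests use 64 × 64 images, corpora of up to 40 images, and the
  replicate counts stated with each test (100 for null/effect checks, 200
  for coverage); these sizes give stable Monte-Carlo estimates for the
  properties under test.
* Degenerate inputs are rejected loudly: empty images or masks, quadrant
  sets with no members, fewer than 2 curves to bootstrap, fewer than 3
  records to correlate, zero-variance correlations, singular matrices.
* Unreadable images in a corpus directory are skipped with a logged warning
  and counted in the report; an empty corpus is fatal.
* All randomness (generator, bootstrap, pipeline) descends from explicit
  integer seeds; reports are byte-identical across re-runs.

## Known limitations

* The exact cone fundamentals, adapting background, and axis scaling used
  by any particular laboratory are conventions; absolute coordinate values
  are not comparable across conventions, only within one configuration.
* The chromogram averages sRGB-encoded values (what a renderer displays),
  not linear light; this is a visualization choice, configurable in
  principle but not exposed.
* Percentile bootstrap bands are known to undercover slightly at small
  corpus sizes; no BCa or studentized correction is applied.
* The generator places each fruit blob at a single hue and a single radial
  contrast; it does not emulate within-object saturation gradients.
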