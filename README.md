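# chromacontrast

Color statistics of image corpora in cone-opponent (DKL) space.

`chromacontrast` compares the *relative chromatic contrast* of warm-colored
(object-like) versus cool-colored (background-like) image regions between two
image corpora — for example, still-life paintings versus photographs of the
same subject matter.  The scientific question it supports: do depictions made
from memory-laden perception (paintings) exaggerate the saturation of the
objects they depict relative to veridical captures (photographs)?  Warm
red–orange–yellow pixels serve as a proxy for objects/fruit; cool pixels as a
proxy for backgrounds.

## Method

1. **Color space.** Each sRGB image is decoded to linear light, mapped
   RGB → XYZ → LMS (Hunt–Pointer–Estévez fundamentals, D65), and expressed as
   cone contrast relative to a mid-gray adapting background on three DKL axes
   (lights convention): achromatic *L/M/S*, chromatic teal–cherry *L/M*, and
   chromatic violet–lime *S*.  Each chromatic axis is scaled so the most
   saturated RGB-cube corner maps to magnitude 2.
2. **Joint histograms.** Per image and per cardinal plane pair, a 128 × 128
   histogram over [−2, 2]², normalized by the image's pixel count; corpus
   summaries are binwise means.  A *chromogram* colors each occupied bin
   with the mean color of its pixels.
3. **Chromatic contrast curves.** Each bin's chromatic contrast is its
   center's distance to the origin, rounded to 4 decimals (1,464 unique
   levels on the default grid).  Histogram mass is summed per level over a
   quadrant subset and divided by the subset's bin count, so quadrant 1
   (warm) is directly comparable to quadrants 2–4 combined.  Curves are
   smoothed with a unit-sum Gaussian (σ = 10 samples) for display.
4. **Bootstrap bands.** The corpus-mean curve gets a 95% percentile band:
   resample N per-image curves with replacement 1,000 times and take the
   25th and 975th sorted means per contrast level.
5. **Warm-excess statistic.** The first moment over contrast of the mean
   Q1-minus-rest difference curve, Σ꜀ c·(d₁(c) − d₂₃₄(c)) — positive when the
   warm quadrant carries relatively more high-contrast mass.  A blue-quadrant
   control (Q3 vs Q2 in the S-vs-achromatic plane) checks that any effect is
   specific to warm colors.
6. **Local differences.** Each image is center-cropped, resized to 256², and
   converted to (L, u′, v′); the mean 8-neighbor Euclidean distance in (u′, v′)
   and in L give one chromatic and one achromatic difference per image,
   correlated per corpus (Pearson).

A seeded synthetic still-life generator (warm elliptical blobs on a cool
background, authored directly in DKL with exact ground truth) makes every
stage testable without image downloads.

## Worked example

```python
import chromacontrast as cc
from chromacontrast.contrast_curves import WARM, REST, contrast_curve, warm_excess_statistic
from chromacontrast.joint_histograms import ISOLUMINANT, compute_joint_histogram

cfg = cc.ColorSpaceConfig()
params = cc.StillLifeParams(width=64, height=64)

for condition in ("painting-like", "photo-like"):
    warm, rest = [], []
    for img, truth in cc.generate_corpus(40, condition=condition, seed=1,
                                         base_params=params, cfg=cfg):
        dkl = cc.srgb_to_dkl(img, cfg)
        hist = compute_joint_histogram(dkl, ISOLUMINANT)
        warm.append(contrast_curve(hist, WARM))
        rest.append(contrast_curve(hist, REST))
    print(condition, warm_excess_statistic(warm, rest))
```

prints (values are in normalized-density × contrast units):

```
painting-like -1.8838757773240456e-06
photo-like -8.479539950688678e-06
```

The painting-like condition (warm saturation gain 1.5) shows a larger
warm-excess statistic than the photo-like condition (gain 1.15): the injected
extra saturation of the warm "fruit" pixels is recovered.  The sign of an
individual value is incidental (it also reflects where background mass sits);
the *difference* between conditions is the effect of interest.

The same analysis runs from the shell on image directories:

```sh
chromacontrast synth --out corpus_a --n 10 --seed 7 --condition painting-like
chromacontrast synth --out corpus_b --n 10 --seed 8 --condition photo-like
cat > run.yaml <<EOF
corpus_a_dir: corpus_a
corpus_b_dir: corpus_b
output_dir: results_run
EOF
chromacontrast analyze --config run.yaml --seed 1
```

which writes `results_run/report.json` plus per-plane histogram tables,
curve tables with bootstrap bands, local-difference records, and plots.

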