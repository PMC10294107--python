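# Methods

## Problem and pipeline

Seed-quality inspection needs one image per seed, but trays are
photographed whole and seeds frequently touch. A global threshold then
merges touching seeds into a single foreground component. The pipeline
treats this as a morphology problem: the contact between two convex seeds
that merely touch is a thin bridge of foreground pixels, and erosion with a
structuring element wider than the bridge removes it while leaving the
(much wider) seed bodies connected. The stages are enhancement,
thresholding, localization, contact judgment, separation, and extraction;
each is exposed as a library function and composed by `run_pipeline`.

## Enhancement (MSRCR)

Multi-scale retinex with color restoration. Per channel the single-scale
response is `log(I+1) − log(G_σ∗I+1)` — natural log with a +1 offset so
zero-valued pixels are safe — summed over surround scales with weights,
multiplied by the color-restoration factor
`β·[log(αI+1) − log(I_R+I_G+I_B+1)]`, and mapped linearly to 0–255 by
clipping at percentiles of the response.

Parameters (all overridable via `RetinexParams`):

| parameter | default | meaning |
|---|---|---|
| scales | 15, 80, 250 px | Gaussian surround standard deviations |
| weights | ⅓ each | per-scale weights, must sum to 1 |
| alpha | 125 | color-restoration strength |
| beta | 46 | color-restoration gain |
| stretch | 1% / 99% | percentile clip bounds of the output map |

These are the canonical defaults of the retinex literature; the choice of
per-channel percentile stretching (vs. a joint stretch over all channels)
is genuinely open, so both are provided with per-channel as the default.

The Gaussian surround is truncated at 3σ and edges are reflected, so
constants are preserved exactly and borders show no dark halo. It is
computed as a separable FFT convolution on a reflect-padded copy: at
σ = 250 on a megapixel scene a direct spatial convolution is orders of
magnitude slower for identical output (to floating-point round-off; the
test suite checks byte-identity of the final 8-bit image against a dense
straight-line reference on small scenes).

A flat response channel (e.g. a constant input scene, whose retinex
response is identically zero) has no percentile range to stretch and is
mapped to the constant 127.

## Thresholding and localization

Grayscale uses ITU-R 601 luma weights. The Otsu threshold is the argmax of
the between-class variance ω₀ω₁(μ₀−μ₁)² over all 256 candidate levels,
computed from cumulative moments; ties break toward the lower threshold,
and a histogram with fewer than two occupied bins (blank scene) is a
degenerate input, reported as such rather than guessed at. Foreground is
"brighter than t"; a polarity flag inverts the grayscale for dark-object
scenes.

Components use 8-connectivity. "Minimum bounding rectangle" is read as the
tight axis-aligned bounding box (the crops are axis-aligned squares; a
rotated minimum-area rectangle would not change what is cropped).
Components smaller than 16 px are discarded as specks before the scene
median is computed, then anything below 0.1 × median component area is
dropped as debris.

## Contact judgment

Touching clusters are a minority of components, so the scene-median box
area robustly estimates the single-seed size. A component is flagged as a
cluster iff its box area exceeds 1.5 × the reference area **or** its longer
side exceeds 1.4 × √reference. The side rule catches two-seed clusters
whose box area stays under the area threshold (e.g. two small seeds joined
along their minor axes). Both ratios and an explicit calibrated reference
are configurable.

## Separation

**EOP** erodes the cluster (masked to its own connected component) with a
filled square kernel, default 13×13, relocates components, and expands each
relocated box by the kernel radius (k−1)/2 per side, clamped to the scene —
square-kernel erosion shrinks every object by exactly that margin, so the
expansion recovers the pre-erosion extent. A cluster that erodes away
entirely is returned whole and flagged, never dropped. Masking the cluster
to its component (not just its rectangle) matters: the rectangle may clip
corners of neighboring seeds, and those alien fragments would otherwise
survive separation as spurious outputs.

**WA** computes the Euclidean distance transform of the cluster, takes its
local maxima with a minimum separation as markers — the standard recipe for
touching convex objects — and runs marker-based watershed; basins partition
the cluster foreground exactly. The minimum marker separation defaults to
half the scene-median seed side, a scale at which one elongated seed
produces one marker but two touching seeds produce two.

EOP splits a pair only when the kernel is wider than the contact bridge;
this is the mechanism behind the accuracy-vs-kernel trend on the benchmark
(3-px bridges survive a 3×3 kernel, so pairs stay merged and are counted
improper).

## Extraction

Crops are taken from the enhanced scene (a flag selects the raw scene
instead), expanded by a 2-px context pad, embedded centered in a square
canvas filled with the scene's median background color — avoiding the hard
artificial edge black margins would create — and resized to 227×227 with
area averaging when shrinking (bilinear when enlarging). Coordinates are
0-based, x = column, boxes half-open `[x, x+w) × [y, y+h)` throughout.

## Accuracy metric

`Acc = n_proper / n_total` over segmented outputs. "Properly segmented" is
a one-to-one greedy match (descending IoU) against ground-truth seed boxes
at IoU ≥ 0.5 — the standard detection criterion; merged clusters and
fragments both fail it. Because the denominator is outputs, a missed seed
does not lower Acc; recall (matched truths / all truths) is reported
alongside as a diagnostic. The exact rational n_proper/n_total is kept next
to the float. Greedy matching can in principle differ from the optimal
assignment; on benchmark-like instances the tests compare it against an
exhaustive assignment oracle and find no disagreement.

## Synthetic scenes

The generator emulates the photographs the pipeline targets: bright convex
soybean-hued blobs on a dark background. Seeds are rotated ellipses with
semi-axes uniform in 22–34 px on a 1024×683 canvas (a 3:2 scale-down of the
3072×2048 camera frames, with seed size scaled by the same factor; full
size is one config field away). Placement is dart-throwing under a
conservative bounding-circle rule guaranteeing ≥ 4 px background between
non-designated seeds. Each designated touching pair is placed with an 8-px
boundary gap spanned by a drawn bridge, 3 px wide by default — drawing the
bridge explicitly, rather than overlapping the ellipses, controls the
contact width exactly, which is the regime kernel-vs-bridge separation is
about. Scenes get a per-seed color jitter (±18 around an ochre base), a
linear multiplicative illumination ramp (max ±7.5%), additive Gaussian
noise (σ = 4), and 8-bit quantization. Everything is driven by one RNG
seed; benchmarks written to disk store scenes as PNG and ground truth as
JSON with run-length-encoded masks, plus a manifest of per-scene seeds.

What the generator does **not** model: specular highlights, soft shadows
between adjacent seeds, seeds overlapping in depth, dust and debris
textures, chromatic camera noise, and seeds of the five quality classes
(color variants exist for visual realism only and carry no class
semantics). Passing benchmarks here therefore shows that the pipeline's
logic — thresholding, localization, contact judgment, bridge-breaking,
compensation, metric — is correct under controlled contrast and contact
geometry, not that the specific accuracy figures transfer to any particular
camera rig.

The foreground/background luma contrast is kept ≥ 5 noise sigmas by
construction (asserted in tests), which is what makes Otsu separation
near-exact on synthetic scenes. The contrast-restoration property of MSRCR
is asserted on a deliberately low-contrast generator variant (dim seeds,
strong illumination ramp): on the standard near-binary scene the raw
normalized contrast is already at its ceiling, so the property is vacuous
there — an intrinsic feature of range-normalized contrast, not of the
enhancement.

## Benchmark sizes and determinism

The standard benchmark is 50 scenes × 40 seeds (20% of seeds in pairs → 4
pairs/scene, 2000 seeds total), the scale at which the accuracy statistics
stabilize while a full sweep (five erosion kernels plus watershed) stays
comfortable on a single CPU; enhancement is computed once per scene and
shared across separation configs, since it does not depend on them.
Repeated runs with the same config are byte-identical: all randomness flows
from explicit integer seeds, per-scene seeds are spawned deterministically
from the master seed, and no stage uses unordered iteration.

## Known limitations

- Contact-judgment thresholds assume clusters are a minority; a scene that
  is mostly one giant clump defeats the median reference (an explicit
  calibrated reference exists for that case).
- Erosion-based separation fails for contacts wider than the kernel and for
  seeds whose minimum width is below the kernel (the cluster is then
  returned whole and flagged).
- The IoU-0.5 criterion can accept a merged pair as "proper" when one seed
  dominates the pair's joint box (observed rarely on the benchmark at small
  kernels); stricter thresholds are configurable.
- Greedy matching is not guaranteed optimal for pathological overlaps,
  though no disagreement with the exhaustive oracle appears at benchmark
  geometry.
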