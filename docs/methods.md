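# Methods

## Overview

The pipeline measures how two monocular depth cues — Lambertian shading and
attached shadows — shift a classifier's (or observer's) reliance on shape
versus texture.  Matched stimulus pairs are constructed so that the 3D and
2D versions of a stimulus are identical except for the presence of those
cues inside the silhouette; every downstream statistic compares behavior
across that manipulation, optionally stratified by whether the object is
seen from a canonical viewpoint.

## Synthetic stimuli

**Shapes.**  Ten object categories each own a parametric part-based mesh
family (assemblies of boxes, cylinders, cones and icospheres — a winged
body, a quadruped, a domed helmet, a slab phone, ...).  Each model draws
its part dimensions uniformly from per-category ranges held in
`data/shape_families.json`, so models within a category share part topology
and differ in proportions.  Meshes are centered and scaled to a unit
bounding-sphere radius (camera framing then never depends on the family),
stay below 2,000 triangles (cheap exact shadow rays), and carry a unit
`front_axis` (+X by construction) used for viewpoint labeling.  All
generators are pure functions of `(category, count, seed)`.

These families are deliberately *not* miniature animals or furniture; they
are category-distinct silhouette/part structures.  A fixed nearest-centroid
read-out on silhouette moment features separates held-out models at well
above the 70% gate the test suite enforces, which is what downstream
analyses need: that shape category is decodable from shape alone.

**Textures.**  Each category owns a periodic pattern family (stripes,
checks, dots, gratings, torus-periodic noise) with a category-specific base
hue; per-texture variation draws pattern frequency, saturation and hue
jitter from the seed.  Patterns are sampled on an inclusive-endpoint
periodic grid — the first and last row/column are equal to ~1e-9 — so
patches tile seamlessly (the duplicated wrap row is dropped when tiling).
Every pixel is texture content; there are no background pixels.  Mean-RGB
plus orientation-energy features separate the ten texture categories at
well above 90% on held-out seeds.

**Canonicality.**  A viewpoint is *canonical* when the camera azimuth lies
within `profile_tolerance` (default 31°) of the object's front direction or
of either profile (front ± 90°), and *noncanonical* otherwise (rear-facing
views).  With the default tolerance a 12-view orbit labels the views at
{0, 30, 60, 90, 120, 240, 270, 300, 330}° canonical — 9 canonical and 3
noncanonical per orbit.  The original study hand-labeled canonicality per
image and reported only the aggregate split; the angular rule is the
reproducible operationalization, and the tolerance is configurable.

## Renderer

A plain perspective rasterizer: look-at camera on an orbit (default
elevation 15°, distance 4 object radii, field of view sized so a
unit-radius object fills the frame with a 1.25× margin), depth-buffered
triangle fill, perspective-correct barycentric interpolation of smooth
vertex normals (vertex normals from trimesh).  Default output 224×224;
tests run at 64×64.

Shading follows a single directional light plus ambient term:

    value = ambient + (1 − ambient) · max(0, n·(−l)) · visibility

with `ambient = 0.1` by default and the light 30° in azimuth and 30° in
elevation off the camera axis (the original study did not report its
lighting; these are explicit, configurable choices).  `visibility` is 0
when a ray from the surface point toward the light re-enters the mesh —
an attached shadow.  The shadow mask records exactly those light-facing,
occluded pixels; back-facing pixels receive only the ambient term and are
*not* counted as attached shadow.

Occlusion is a vectorized Möller–Trumbore test of every shadow ray against
every triangle, chunked over rays.  At ≤2,000 triangles this is fast,
exact, and directly checkable against an independently written per-ray
plane-intersection oracle, which the test suite does pixel for pixel.
Shadow-ray origins are offset 0.015 radii along the interpolated normal
(`SHADOW_BIAS`): interpolated surface points lie on the polyhedral facets,
up to a chord's depth below the smooth surface they approximate, and
without the offset grazing rays near the shading terminator stipple convex
surfaces with spurious shadow.  The bias is far smaller than any part
dimension in the shape families.

Silhouettes come from the *same* rasterization call, so a shaded render and
its silhouette have pixel-identical figure masks — the property that makes
the two conditions differ only in shading/attached-shadow content.

## Datasets and texture substitution

Texture substitution is performed in image space, not UV space: the texture
is tiled (seamlessly, via the wrap row) and center-cropped to the frame,
then multiplied pixelwise into the render — by the shaded grayscale for the
3D condition, by the binary silhouette for the 2D condition.  Consequences
used as test invariants: 2D equals 3D applied to a mask-valued shading;
3D pixels never exceed their 2D pair; 3D pixels stay ≥ ambient × 2D
wherever the surface faces the light unshadowed.

`build_dataset` enumerates mesh × viewpoint × texture × condition (the
full-scale grid is 100 × 12 × 100 × 2), labels canonicality, and returns a
CSV-serializable manifest; `materialize=None` skips all pixel work so
full-scale combinatorics are verifiable in seconds.  Congruent records
(shape and texture category equal) are generated but flagged, and excluded
by default from bias statistics, where texture-correct is ill-defined.

## Evaluation

Classifiers emit probability vectors over a fine-grained vocabulary; a
shipped two-column table maps each subcategory label to one of the ten
entry-level categories.  Scores are summed per entry-level category and the
decision is the argmax (ties broken lexicographically and logged; mass
entirely on unmapped labels yields decision `none`).  On incongruent
stimuli the decision is scored shape-correct, texture-correct, or other;
`texture_bias = n_texture / (n_texture + n_shape)` is undefined (reported
as missing) when no cue-correct trials exist, and is by construction
invariant to the number of `other` outcomes.  Percentages are rounded half
away from zero.  Condition metrics report per-(condition × canonicality)
accuracies and bias; 3D gains are computed on matched (shape, texture,
viewpoint) pairs present in both conditions.  Record-level oracle
classifiers (shape, texture, mixture(p), uniform) are the pluggable test
doubles; real models plug in as probability matrices plus a vocabulary.

## Behavioral simulation and analysis

Experiment 1: a 160-trial shape-identification block (8 stimuli × 10
categories × 2 conditions, shuffled) then a symmetric texture block; every
trial is incongruent by construction; 10 flagged practice trials precede
each block.  Experiment 2: shape task only, 20 trials per (condition ×
canonicality) cell, 80 trials shuffled, 16 practice trials.  Schedules are
deterministic under a seed; insufficient cells raise with the cell named.

Observers are simulated at cell level: correct with the cell's accuracy,
otherwise uniform over the nine wrong categories; an optional lapse rate
guesses uniformly over all ten; response times are log-normal per cell.
Accuracy is analyzed on per-subject cell means with a fully within-subject
2×2 ANOVA, each effect tested against its own subject-by-effect stratum;
partial η² = SS_effect/(SS_effect + SS_error); paired contrasts report the
mean difference, t (df = S−1), and Cohen's d of the paired differences.
Sphericity is not at issue for 1-df effects.  Sums of squares below a
~1e-12 relative floor are treated as zero so constant tables report F = 0
rather than float noise.  The implementation agrees with pingouin's
repeated-measures ANOVA to ~1e-9 and with a textbook cell-loop
decomposition to 1e-8 on random tables.

## Finetuning protocol

Four curricula cross an image filter with a freeze policy (all trained on
3D-condition stimuli only): all-views/unfrozen (lr 2e-5), all-views/head
only (lr 1e-3), canonical-only/unfrozen (2e-5), canonical-only/head-only
(1e-3); batch size 96.  The filter applies before the 80/20
train/validation split, which is stratified by shape category and
deterministic under the seed.  Training stops at the first epoch whose
validation error exceeds the previous epoch's (or at `max_epochs`), and the
adopted model is the checkpoint with minimum validation error.  Validation
is checked once per epoch; batch order reshuffles each epoch from the run
seed's stream; the last partial batch is kept.  Optimizer is plain SGD (the
original optimizer being unreported), configurable via the model contract.

The reference classifier is a small two-stage network: a tanh feature stage
over 16×16 block-sampled grayscale pixels and a linear softmax head.
`freeze("head_only")` pins the feature stage bit-exactly — the linear-probe
regime.  Feature columns are z-scored over the dataset when loading
(constant background pixels are scaled out); without this conditioning,
plain SGD's epoch-to-epoch noise triggers the first-increase stopping rule
long before convergence.  The preset learning rates above assume a
pretrained backbone being nudged; protocol experiments that need the
scratch reference model to actually learn use custom `Curriculum` objects
with lr ≈ 0.1, at which both freeze policies show smooth validation curves
and stop at genuine convergence.

## What the synthetic data does and does not show

The generators reproduce the *design* of the original stimuli — category
structure, counts, viewpoint orbit, matched 3D/2D pairs, canonicality
labeling — with category signal known by construction.  They do not
reproduce natural shape statistics, photographic texture, or the visual
diet of pretrained networks; and the reference classifier is a scratch
model, not a pretrained transformer.  Passing tests therefore certify the
pipeline's correctness (combinatorics, rendering physics, statistics,
protocol rules) and the internal consistency of the published arithmetic,
not the published networks' accuracies, which depend on external assets
and weights out of scope here.

## Problem sizes used in tests

Full-scale combinatorics run lazily (no pixels).  Materialized fixtures use
2 models and 2 textures per category at 12 views and 64×64 (a 9,600-image
grid built once per test session), and a 4-model × 12-view × 6-texture
miniature (576 images) for the pixel-level invariants.  Calibration checks
use 5,000-trial subsamples with 3-standard-error bands; the ANOVA power
check uses 200 replicates of 129 simulated observers.
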