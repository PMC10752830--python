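# Methods

This note records the models, parameter choices and numerical conventions
behind `lungmorph`, and what the synthetic validation does and does not
establish about real tissue.

## The measurement model

An *air space* (AS) is an intra- or extra-alveolar air collection of at
least 100 µm² in a calibrated RGB brightfield field. Per field the pipeline
reports the count (CAS), total air area (AAS, µm²), percentage of field
area (PAS = 100·AAS/field area), and per object the maximum and minimum
Feret diameters (MaxDAS, MinDAS, µm). Per case, field summaries are
averaged; the area-per-air-space ratio is the per-field AAS/CAS averaged
over fields with CAS > 0 (a mean of ratios — this is what reconciles the
reported ratio level with the reported AAS and CAS levels, which a ratio of
means would not). Diameter summaries are object-weighted: each field's mean
is weighted by its CAS, which equals the mean over all objects of the case.
Fields with CAS = 0 enter the CAS/AAS/PAS means but are excluded from ratio
and diameter means. Edge-truncated objects are measured as-is, with no
boundary correction.

## Segmentation

The detector composes:

1. **Adaptive red-channel threshold.** Candidate air requires
   `red ≥ local_mean(red, w) + offset` with window `w` = 301 px and offset
   −10 by default. The local stage absorbs illumination gradients; on flat
   fields it is nearly neutral.
2. **Automatic binarization.** Otsu's threshold on the red histogram,
   accepted only when the two classes it induces have mean separation
   ≥ 20 grey levels. A unimodal histogram (uniform stain, or bare sensor
   noise) makes Otsu's split meaningless; in that case an absolute
   unstained-red floor (default 225) decides. This preserves the intuitive
   limits: a uniformly eosin-stained field contains no air, a uniformly
   unstained field is one full-field air space.
3. **Chromatic artifact exclusion.** Candidate air pixels are dropped when
   |R−B| > 25 (pale oedema / residual eosin tinge), when R−G > 60 at mean
   brightness < 130 (erythrocytes), or when B−R > 30 (hematoxylin-stained
   nuclei). All thresholds are config fields.
4. **Morphological opening** with a configurable disk radius, default 0
   (identity). With hard-edged staining boundaries and the 100 µm² filter
   already suppressing speckle, a nonzero default would only bias areas
   downward relative to ground truth.
5. **Connected components** (8-connectivity by default, the particle-
   analysis convention) and the **minimum-area filter** in physical units
   (pixel count × µm²/px² ≥ 100 µm²). Labels are re-indexed consecutively
   in scan order; border contact is flagged per object.

Manual artifact correction is a binary mask whose pixels are forced out of
every object, followed by relabeling and re-filtering — masking can remove
an object, or split one into two retained objects.

Open conventions resolved here: the threshold targets the unstained
(air) phase, i.e. parenchyma is the complement; "automatic binarization" is
implemented as Otsu.

## Feret diameters

Coordinates are pixel centers (row, col), origin top-left. The maximum
Feret diameter is the largest pairwise distance between boundary-pixel
centers, computed on the convex hull (hull vertices suffice; verified in
tests against exhaustive boundary-pair search). The minimum Feret diameter
is the exact minimal caliper width of the hull: the minimum over hull edges
of the farthest vertex distance to the edge's supporting line (the minimal
width of a convex polygon is attained perpendicular to an edge, so no
angular scan is needed; tests compare against a 0.01° rotation scan).
Degenerate objects (single pixel, collinear pixels) floor both diameters at
one pixel so diameters stay positive. A consequence of the pixel-center
convention: a 10×10 px square at 1 µm/px has max Feret 9√2 ≈ 12.73 µm.

## Group statistics and ROC

One-way ANOVA (sums of squares) with post hoc pairwise t contrasts using
the pooled within-group variance (MSE, N−k df) and Bonferroni correction,
by default against the drowning reference (m = k−1 comparisons; all-pairs
scope available). Shapiro–Wilk per group and Levene across groups are
reported descriptively and never gate the parametric analysis. Degenerate
inputs (zero total variance, or a group with a single case in micro-runs)
yield a descriptive table with no significance flags.

ROC analysis orients every parameter as higher ⇒ barotrauma-positive, and
pools all non-positive groups as controls. Thresholds are midpoints between
adjacent distinct pooled values plus ∓∞ sentinels; sensitivity is the
fraction of cases strictly above the threshold, specificity the fraction of
controls at or below it. The AUC is the Mann–Whitney pair-counting
statistic (ties ½), computed from ranks; it equals the trapezoidal area
under the empirical curve *in threshold order* (sorting points by false-
positive rate breaks tied-rate runs and is avoided). The p-value against
AUC = 0.5 uses the exact rank-sum null for tie-free problems up to 10⁴
case-control pairs (the study scale is 6 vs 12) and the tie-corrected
normal approximation otherwise; the exact recursion is numerically unusable
near 10⁶ pairs. The cut-off maximizes Youden's J = sensitivity +
specificity − 1, with ties broken toward higher sensitivity and then lower
cut-off; the criterion is configurable in principle since the original
choice is not documented.

## Synthetic tissue generator

Each field is a Voronoi tessellation of Poisson-distributed seed points
(density in points/mm²), with walls realized as thickened bisectors: a
pixel is wall when its distance to the nearest seed of a *different* region
exceeds its own-seed distance by less than the wall thickness, giving
uniform physical wall thickness along every retained edge. Over-distension
is emulated by deleting a fraction of Delaunay-adjacent wall segments and
merging the cells they separated (union-find). Wall deletions are coupled
across merge fractions — each edge carries one uniform draw, deleted when
it falls below the fraction — so increasing the merge fraction is a nested
coarsening and mean true air-space area is monotone in it. Artifacts are
discs stamped onto air pixels: oedema (radius 15–40 µm), vessels/
erythrocyte pools (10–25 µm) and intra-alveolar cell clusters (6–15 µm), at
per-mm² densities. Rendering maps labels through a five-color stain palette
and adds clipped per-channel Gaussian noise (default SD 6/255, a
configurable stand-in for sensor noise). Randomness is split into
independent child streams (seeds, wall deletion, artifacts, noise) from one
field seed; cohort sub-seeds derive deterministically from a master seed
and the (group, case, slide, field) indices, so cohorts are reproducible
and fields independent.

All structural parameters are physical (per-mm², µm), with seed points
sampled in µm coordinates, so ground-truth areas are calibration-
equivariant to within rasterization error (≈2 %).

**Group presets.** Calibration is end-to-end: because the measured PAS
depends on the detector, preset centers were grid-searched so the
*pipeline-measured* PAS approaches the published group levels (≈65 / 38 /
42 %). Frozen values — barotrauma: density 48 ± 8 /mm², merge fraction
0.45 ± 0.10, wall thickness 56 ± 8 µm; drowning: 66 ± 10, 0.06 ± 0.04,
47 ± 3.5; control: 72 ± 12, 0.06 ± 0.04, 42 ± 9 (case-level truncated-
normal draws). The barotrauma preset has strictly more wall deletion and
fewer seed points, encoding confluent over-distension. Between-case spreads
give PAS variability comparable in relative terms to the published cohort.

**Problem sizes.** The generator defaults to the full 4000×3000 px field at
0.33 µm/px (≈1.31 mm², chosen because the published AAS and PAS levels
imply a field area of ≈1.31×10⁶ µm²; the acquisition hardware's calibration
is not documented, so this is a consistency inference). The validation
suite and the simulated studies run at 256×192 px and 1.4 µm/px (≈0.096 mm²
per field) — PAS and the preset calibration are scale-free, and this size
lets twenty full 6/6/6 studies (4 slides × 6 fields per case, 432 fields
each) run as part of the routine test suite. Large simulated studies run
through an in-memory pipeline path (`run_synthetic_study`) that composes
generation and analysis without writing image files; the disk-backed
manifest pipeline is exercised on small cohorts.

**What the synthetic validation shows — and does not.** Passing the
segmentation oracle (IoU ≥ 0.85, exact object-count recovery with a 20 µm²
rasterization guard band) and the parameter-recovery study (the barotrauma
vs drowning contrast in AAS and PAS flagged at p < 0.01 and PAS AUC ≥ 0.9
in ≥ 18/20 master seeds) establishes that the measurement chain is
self-consistent and that group differences of the published magnitude
survive the whole pipeline at the published sample size. The generator does
not model nuclear texture, stain variability across laboratories, tissue
folds, compression artifacts, or genuinely ambiguous air/oedema boundaries;
performance on real slides therefore still requires the manual-correction
step the workflow provides, and the color-rule thresholds may need
re-tuning per scanner.

## Distribution-level consistency with the published tables

The published per-case group summaries (means/SDs of the five diagnostic
parameters for 6 barotrauma, 6 drowning, 6 control cases) and the published
AUCs are linked by a reproducible computation: drawing large normal samples
from the group summaries and computing the pooled-control pair-counting AUC
yields values at or slightly above the published ones for mean AAS, mean
PAS, AAS/CAS and minimum DAS (binormal theory puts them at ≈0.954, 0.954,
0.931 and 0.841). `scripts/acceptance.py` performs exactly this computation
(n = 10,000 per group, seeded). The published numbers themselves come from
18 real cases whose images are not public, so exact reproduction is not
possible; distribution-level consistency is the strongest check available.

## Known limitations

- The eligibility filter trusts manifest metadata; it cannot detect, e.g.,
  undocumented resuscitation.
- MinDAS is the least discriminating parameter in the published data and
  the noisiest in simulation; its recovery tolerance is correspondingly
  loose.
- The per-field ratio AAS/CAS is undefined for fields without air spaces;
  such fields are excluded from the ratio mean, which biases the ratio up
  slightly in nearly airless tissue.
- Whole-slide imaging, stain normalization and learned segmentation are out
  of scope.
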