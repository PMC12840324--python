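# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `nodeval`.  It covers the evaluation pipeline itself
and the synthetic phantom generator whose parameters are calibrated to a
published 125-scan head-and-neck CT cohort (3656 annotated cervical
nodes, 544 metastatic).

## Coordinate and measurement conventions

Volumes are integer grids with axes ordered (x, y, z); axis 2 is the
axial (slice) axis, which matters because the short-axis diameter is a
per-axial-slice measure.  Voxel indices are 0-based; physical positions
are voxel-center based (`index × spacing`, mm).  Spacing is anisotropic
and carried through every distance computation; no resampling is ever
performed — clinical node masks live on 0.75–2.5 mm slices and
resampling a label mask would alter the very quantities being measured.

## Short-axis diameter (SAD) estimator

RECIST 1.1 measures nodal lesions by the short axis on an axial slice.
On a voxel mask there is no single canonical estimator, so the package
defines one and documents it:

For each axial slice intersecting the instance: (1) collect in-plane
voxel centers (mm); (2) the *long axis* is the maximal caliper — the
center pair at maximal distance (convex-hull vertices suffice); (3) the
*short axis* is the extent of center projections onto the perpendicular
direction, plus one in-plane voxel dimension.  The instance SAD is the
maximum over slices, floored at one in-plane voxel.

Choices worth flagging:

* **+1 voxel correction.**  Center-to-center extents underestimate the
  physical extent of the voxel union by one voxel; the correction makes a
  single voxel at spacing (1, 1, 2) measure 1.0 mm and keeps digital
  spheres within one in-plane voxel of their analytic diameter across
  spacings (verified for (1,1,1), (1,1,2), (0.7,0.7,2.5)).
* **Max over slices**, not the SAD at the largest-area slice: this is
  deterministic and stable under slab repositioning, but can exceed a
  radiologist's single-slice measurement for tilted elongated nodes.
* A minimal-Feret-width variant (`method="min_feret"`) is available for
  comparison; it ignores the long-axis convention and is not the
  canonical measure.

## Matching model

Matching is ground-truth-centric.  Per GT instance, *sensitivity* =
|GT ∩ Pred| / |GT|; the node is *localized* when sensitivity ≥ 0.4
(boundary inclusive).  No one-to-one assignment is attempted because
confluent nodal disease makes instance bijections ill-defined; a single
merged prediction covering two touching nodes legitimately localizes
both.  On the prediction side, a component is a *false positive* when
less than 40% of its voxels lie on GT foreground.  The FP threshold is
chosen symmetric with the localization threshold as the least-surprising
default; both are configuration fields (`tau_localize`, `theta_fp`), as
is the 4.5 mm prediction size filter (`min_pred_sad_mm`), which is
applied before any matching.

Degenerate conventions: a scan with no predictions and no GT nodes has
precision 1.0; with GT nodes but no predictions, precision is undefined
and reported as missing (never zero).  F1 is 0 when recall = precision
= 0 and missing when either input is missing.

## Segmentation metrics on filtered masks

Global Dice and the average Hausdorff distance are computed after
removing missed GT instances and FP predictions, so they measure boundary
quality on attempted tissue rather than re-penalizing detection errors.
"Average Hausdorff distance" is implemented as the symmetric average
surface distance: mean distance (mm) from each boundary voxel of one mask
to the other mask's boundary, averaged over both directions.  A boundary
voxel is a foreground voxel with a background 6-neighbor.  A sub-voxel
cohort value of this metric is only achievable by an averaged — not
maximal — surface distance, which motivates the choice; directed variants
are available via `hausdorff_variant`.  The metric is undefined (null,
with a warning) when either filtered mask is empty.  Dice is 1.0 when
both masks are empty and 0.0 when exactly one is.

## Cohort statistics

Macro recall (mean of per-scan recalls) and micro recall (pooled over
nodes; identical to the node-count-weighted mean of stratum recalls) are
both always reported and labelled, since they differ whenever node counts
vary across scans.  Group comparisons use Kruskal–Wallis at α = 0.01
after a Shapiro–Wilk normality screen; the recall comparison is applied
to per-node binary localized indicators by default (the unit of analysis
is configurable to per-scan recalls).  Post hoc pairwise comparisons are
two-group rank tests with raw p-values by default; Holm correction is a
flag.  Shapiro–Wilk for n > 5000 uses a deterministic sorted-strided
subsample of 5000 values.  All-identical data yields H = 0, p = 1
("no evidence of a difference") rather than an error.

## Synthetic cohort generator

The generator emulates the *statistical structure* of the reference
cohort, not node anatomy:

* **Scans** are (160, 160, 80) grids at (1, 1, 2) mm spacing; node count
  per scan is Poisson with mean 29.2 (at least 1).
* **Nodes** are randomly oriented digital ellipsoids.  Shapes are
  analytically controllable — which is exactly what validation requires —
  but they lack real nodes' irregular margins, hilum, and partial-volume
  boundaries.
* **Sizes**: per nodal status (metastatic fraction 544/3656), target SADs
  follow a log-normal truncated to [3 mm, observed maximum] whose
  parameters are fitted by least squares to the reference per-status
  stratum counts (<5 / 5–10 / 10–15 / >15 mm).  The fitted truncated
  means (4.91 / 11.09 mm) reproduce the reference per-status means
  (5.0 / 11.3 mm) within ~2% as a free check.  The 3 mm floor is a
  rasterization requirement (smaller blobs are not meaningfully
  measurable at 1 mm in-plane spacing).
* **Calibrated rasterization**: small digital ellipsoids measure below
  their nominal SAD, so the short semi-axis is iteratively nudged (≤3
  re-rasterizations) until the *measured* SAD of the digital mask is
  within half an in-plane voxel of the target.
* **Clusters**: with probability `cluster_probability` (default 0.05) a
  node gets a touching same-status companion; contact is guaranteed by
  spacing centers at 0.7× the sum of short semi-axes.
* **Necrosis**: metastatic nodes with SAD ≥ 15 mm carry a concentric
  core of 25% of the node volume; the core is ground-truth tissue.

An alternative `sad_distribution="stratified"` draws the size stratum
uniformly and the SAD uniformly within it — used when per-stratum
statistical power matters more than realistic frequencies.

## Degradation model

Predictions are derived from ground truth per instance, in this order:

1. **miss** — the instance is dropped with the miss probability of its
   measured SAD stratum (defaults 0.28 / 0.21 / 0.33 / 0.64, the
   complements of the reference per-stratum recalls).  Misses are drawn
   *before* boundary degradation, so realized per-stratum recall is
   binomial with known probability;
2. **boundary error** — one-voxel in-plane dilation (p = 0.25) or erosion
   (p = 0.25; radius configurable).  Erosion is restricted to nodes with
   SAD ≥ 10 mm so boundary noise alone can never push a surviving node's
   coverage below the 0.4 localization threshold, preserving the binomial
   recall structure;
3. **necrosis drop-out** — with probability 0.8 a necrotic node's
   prediction excludes the core (the characteristic large-node failure
   mode);
4. **false positives** — Poisson(6.5) blobs per scan, placed with a
   one-voxel clearance from both ground truth and the prediction so far
   (each FP is guaranteed its own component with zero GT overlap).  FP
   sizes are a two-component mixture: a just-above-threshold log-normal
   on [4.6, 10) mm plus a log-uniform large tail on [10, 20] mm with
   weight 0.3/6.5, calibrated so the mixture mean is 5.3 mm.  A single
   log-normal cannot combine a 4.6 mm floor, a 5.3 mm mean and a 4.6%
   tail ≥ 10 mm (numerically, achievable means are ≥ 6.15 mm), so the
   tail is modelled explicitly.  The floor reflects that reported FP
   populations are post-size-filter.

All randomness flows from one cohort seed through spawned per-scan
generators; regeneration is byte-identical.

## Validation protocol (parameter recovery)

The reference cohort's masks are private, so the pipeline is validated by
recovering known generator parameters: simulate 125 scans, evaluate end
to end, and compare measured per-stratum recalls (tolerance ±0.04 at
≥ 200 nodes/stratum) and FPs/scan (±0.5) to the generating values.  Two
deliberate protocol conditions:

* sizes are drawn stratified-uniform so each stratum holds ~900 nodes;
* the 4.5 mm prediction filter is disabled *for this protocol*: a
  surviving node's prediction mirrors its GT component, so for
  sub-filter-sized nodes the filter would add deterministic
  size-dependent misses on top of the miss process being recovered,
  destroying the binomial structure.  The filter is exercised separately
  by unit tests and is on by default in the evaluation configuration.

What passing recovery does and does not show: it validates the
instance/matching/aggregation machinery and the degradation model's
self-consistency; it does not validate SAD measurement against manual
calipers on real nodes, robustness to annotation noise, or behaviour on
non-ellipsoidal morphology.

## Numerical and degenerate-input choices

* Left-closed SAD strata: [0,5), [5,10), [10,15), [15,∞) mm.
* The 4.5 mm filter removes strictly smaller components; 4.5 mm is kept.
* Localization boundary (0.4) counts as localized; FP boundary (0.4
  overlap) counts as matched.
* Empty masks: instance extraction returns no instances; SAD of an empty
  voxel set is an error; undefined report cells are nulls, never zeros.
* Non-consecutive instance labels are rejected on load unless an explicit
  relabel flag is passed.

## Problem sizes

Default test and validation runs use 125-scan cohorts on (160, 160, 80)
grids (the full-loop recovery) and small 3–10-scan cohorts on 96³-scale
grids for workflow tests; brute-force oracle comparisons run on random
masks up to 12³ across 100 seeds.  These sizes give per-stratum binomial
standard errors ≈ 0.015, comfortably inside the ±0.04 recovery tolerance.
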