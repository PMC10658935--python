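# Methods

`dcebench` benchmarks three breast-lesion segmentation methods on dynamic
contrast-enhanced (DCE) MRI: fuzzy c-means (FCM) clustering of the
contrast-uptake time course, a 2D U-Net applied slice by slice (its stacked
output is called the *quasi-3D* segmentation), and a 3D U-Net. Because
clinical DCE-MRI cohorts with lesion annotations are private, the package
runs entirely on synthetic lesion phantoms whose construction is described
below; every quantity the package reports is computed from these phantoms
at run time.

## Synthetic phantoms

A phantom is a 4D series (time, slice, row, col) with one precontrast and
two postcontrast volumes. Signal follows

    S_t(x) = S_0 · (1 + e(t) · M(x) + b(x) · g(t) · (1 − M(x))) + ε_t(x)

with `M` the binary lesion mask, `e(t)` the lesion's relative-enhancement
curve, `b(x)` a smooth background parenchymal-enhancement field, `g(t)` a
persistent-type temporal profile, and `ε` i.i.d. Gaussian noise drawn
independently per timepoint.

Key parameters (defaults in parentheses):

* **Geometry** — volume 18×64×64 voxels at (3.0, 0.8, 0.8) mm; in-plane
  0.5–1.0 mm and slice 1–3.5 mm are the plausible clinical ranges.
* **Timing** — acquisition at (0, 75, 150) s, within the typical 60–75 s
  temporal resolution of breast DCE protocols.
* **Baseline intensity** — 500 arbitrary units; only ratios matter.
* **Noise** — σ = 5 % of baseline per timepoint.
* **Background enhancement** — amplitude 20 % of the lesion peak, spatially
  modulated by a smooth random field (±50 %). This gives FCM a genuine
  two-class problem instead of a trivial one.
* **Kinetics** — benign lesions use a persistent curve (concave rise to a
  peak relative enhancement of 0.8 at the end of the window); malignant
  lesions use a washout curve peaking at 1.2 at 120 s and losing 25 % of
  peak per window length afterwards. No published quantitative
  benign/malignant kinetic parameterization was adopted; these are package
  conventions, exposed in configuration, chosen so that (a) washout peaks
  strictly before the end of the window and (b) second-postcontrast lesion
  enhancement exceeds first-postcontrast enhancement for both classes,
  which makes the timepoint-ordering comparison well posed.
* **Morphology** — *mass* lesions are smoothed, mildly irregular ellipsoids
  thresholded so that the center-slice area matches the requested effective
  diameter `d = 2·√(A/π)` by exact pixel counting (realized diameter within
  one in-plane voxel). *Nonmass* lesions are unions of 3–8 small blobs,
  pairwise separated in-plane so the center slice has ≥ 2 connected
  components, with the same total center-slice area — a minimal surrogate
  for diffuse, scattered enhancement.
* **Cohort composition** — lesion type × pathology proportions default to a
  published 994-lesion clinical series (mass 170 benign / 517 malignant,
  nonmass 49/175, unknown 51/32; "unknown" lesions are rendered as mass or
  nonmass with equal probability), apportioned by largest remainder so each
  realized stratum is within one case of its target. Effective diameters
  are drawn per the same series' size-bin frequencies (<5, 5–9, 10–14,
  15–19, >20 mm), uniformly within bins (3–5 mm for the lowest, 20–26 mm
  for the highest, capped by the volume extent).
* **VOI** — the operator bounding box is the truth-mask support plus a
  margin (3 voxels in-plane, 1 slice axially), mimicking a human operator's
  rectangle-plus-slice-range input.

What the phantoms deliberately do **not** model: breast anatomy, coil/bias
fields, motion, partial-volume boundaries, chest wall or skin enhancement,
multi-focal disease inside one VOI, and interslice gaps. Consequently the
benchmark's absolute scores are far higher than anything achievable on
patient data; passing tests demonstrate that the pipeline's machinery
(features, updates, metrics, statistics, training) is correct and that the
*relative* orderings the designs probe are reproduced, not that any method
would reach these scores clinically.

## FCM surrogate reference

Each VOI voxel is represented by its relative-enhancement vector
`(S_t − S_0)/max(S_0, ε)` with ε = 1 intensity unit, one entry per
postcontrast timepoint. Standard fuzzy c-means (c = 2, fuzziness m = 2,
tolerance 1e−5, ≤ 100 iterations, k-means++-style seeded initialization)
minimizes `J = Σ_k Σ_i u_ik^m ‖x_k − v_i‖²` with row-stochastic
memberships. The lesion cluster is the one with the larger mean centroid
enhancement (never the cluster index, so relabelling cannot change the
output), voxels with lesion membership > 0.5 are kept, the largest
26-connected 3D component is retained and in-plane holes are filled. An
all-empty result is returned flagged *failed* rather than raised. The
published FCM reference configuration is not fully specified anywhere, so
this is a documented surrogate, not a claim about any clinical
implementation.

## U-Net arms

Inputs are postcontrast-minus-precontrast subtraction images cropped to the
VOI and resized in-plane, range-preservingly, to a square model size
(desk-scale default 64×64; 256×256 mirrors the clinical-scale convention).
Slice count is never resampled. Inputs are min-max normalized to [0, 1]
using the whole-VOI subtraction range, so lesion-free margin slices are not
noise-amplified.

The networks are a conventional U-Net encoder–decoder with two 3×3(+3)
convolutions + ReLU per level, 2× max pooling, nearest-neighbour upsampling
and skip concatenation, implemented directly on numpy arrays with
hand-written backward passes (N-dimensional "same" convolution via an
im2col GEMM, max-pool argmax routing, block-sum upsample adjoint). Desk
defaults: 2D — 3 levels, 16 base filters; 3D — 2 levels, 8 base filters,
pooling in-plane only (lesions span too few slices to pool axially; axial
pooling is available by configuration). Training uses Adam (lr 1e−3 with
cosine decay to lr/10 across the run — constant-rate Adam occasionally
left one model poorly converged, which injected pure optimizer noise into
between-arm comparisons), binary cross-entropy on logits, batch 8 for 2D
slices and single volumes for 3D. Training labels default to the FCM
surrogate masks (nearest-neighbour-resized to the model grid); synthetic
truth labels are selectable by configuration.

2D training excludes each lesion's top and bottom VOI slices, which are the
hardest to segment; test-time prediction keeps all slices. Lesions with
fewer than three VOI slices keep all slices in training (strict exclusion
would discard them) and are flagged in the log.

Probability maps are binarized with `p > threshold`, 0.25 for the quasi-3D
arm and 0.23 for the 3D arm — the operating points selected by sweeping
0.14–0.30 in 0.01 steps for the greatest mean Dice coefficient during
training (ties break to the smallest threshold; `calibrate_threshold`
reproduces this sweep). Predictions are brought back to the original VOI
grid by bilinear in-plane interpolation of the probability map *followed*
by thresholding; interpolating before thresholding avoids nearest-neighbour
blockiness (whether the original workflow thresholded before or after
back-resizing is not documented; this choice is ours).

## Metrics

* **DSC** `2|A∩B|/(|A|+|B|)` on volumes and on center slices; two empty
  masks score 1.0 by convention (never triggered by reference masks).
* **Hausdorff distance** per slice, symmetric max–min over 4-connectivity
  boundary pixels, Euclidean in mm with anisotropic in-plane spacing; full
  HD, not a percentile variant. Per lesion, the median over slices where
  both masks are non-empty. If no such slice exists the lesion's HD is
  undefined and the lesion is excluded from HD statistics.
* **Failed segmentations** (all-empty predictions) contribute DSC = 0 to
  DSC statistics and are excluded from HD statistics.
* **Center slice** = floor((first + last)/2) of the VOI slice range (lower
  middle for even counts).
* **Effective diameter** `2·√(A/π)`, A in mm² from the center slice.

## Cross-validation and statistics

Folds are allocated by lesion (never by slice), stratified over
pathology × enhancement type × size bin: within each stratum, lesions are
shuffled (seeded) and dealt round-robin starting at the currently smallest
fold, so per-stratum fold counts differ by at most one.

Paired comparisons use the Wilcoxon signed-rank test (zeros dropped, tied
ranks averaged; exact null distribution by convolution for n ≤ 25, normal
approximation with tie and continuity corrections above). Unpaired
comparisons use the Mann–Whitney U test (exact inversion-count distribution
when there are no ties and n·m ≤ 400, tie-corrected normal approximation
otherwise). Multiplicity is handled by Bonferroni: m = 2 for the
quasi-3D-vs-3D volume design (A), m = 3 for the three pairwise center-slice
tests (B), m = 4 for the timepoint (C) and mass-vs-nonmass (D) grids.
Medians are reported with percentile-bootstrap 95 % confidence intervals
(2000 resamples, seeded); the CI construction for medians is a package
choice.

The four designs:

* **A** — quasi-3D vs 3D volumetric segmentation, FCM as reference, paired.
* **B** — FCM vs quasi-3D vs 3D on VOI center slices against a center-slice
  truth reference (standing in for the radiologist delineation role),
  paired.
* **C** — first vs second postcontrast input per U-Net arm and lesion type,
  paired.
* **D** — mass vs nonmass lesions per U-Net arm and input timepoint,
  unpaired.

A comparison whose paired differences are all zero is reported as
*inconclusive* rather than erroring the run.

## Problem sizes and numerical choices

The default benchmark uses 60 lesions, 64×64 desk-scale networks, 2 trained
folds (every lesion is held out exactly once), 12 epochs for the 2D arm and
7 for the 3D arm — sizes chosen so a complete run finishes in tens of
minutes on one CPU while leaving the orderings of interest resolvable. The
fold-construction and statistics layers are additionally exercised at the
full 994-lesion manifest scale, which is cheap without training.

Degenerate inputs are handled explicitly rather than crashing: VOIs with
nothing enhancing produce failed-flagged empty masks; identical feature
vectors raise a degenerate-data error inside FCM (caught by the
segmentation wrapper); all-zero paired differences raise a degenerate-test
error (reported as inconclusive by the comparison runner). Thresholds are
validated to lie strictly inside (0, 1). Size-bin edges use the half-open
convention (0,5), [5,10), [10,15), [15,20), [20,∞).

## Known limitations

* The phantom world is linearly separable enough that FCM is near-perfect;
  differences between U-Net arms are therefore smaller and cleaner than on
  clinical data, and the 3D arm is not handicapped by the anatomy-driven
  effects that hurt it clinically.
* The numpy networks are CPU-bound and desk-scale; they are not intended
  for clinical-size 256×256×N training.
* Statistical comparisons treat lesions as independent; multiple lesions
  per patient are not modelled (fold allocation is by lesion).
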