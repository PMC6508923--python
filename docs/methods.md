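# Methods

`thighseg` segments dual-contrast thigh MRI — a fat-suppressed (FS) and a
water-suppressed (WS) volume per subject — into whole-tissue masks (thigh,
bone + marrow, total muscle, subcutaneous and intermuscular adipose tissue)
and partitions the muscle into three functional compartments (knee
extensors, knee flexors, medial compartment).  This note documents the
models, the constants that matter, the numerical choices, and what the
synthetic phantom does and does not establish.

## Gray-level model (LCDG)

The empirical distribution of Q = 256 gray levels is approximated by a
*linear combination of discrete Gaussians*: two dominant components (one per
tissue class, dark and light) plus small signed "deviation" components —
`n_add` additive and `n_sub` subtractive (defaults 4/4 for whole-volume
fits, 2/2 for per-compartment fits, where each class is near-unimodal).  A
discrete Gaussian integrates a normal density over unit gray-level bins,
with the end bins absorbing the tails, so each component sums exactly to 1.

Fitting is deterministic:

1. the dominant pair is fitted by count-weighted EM on the histogram,
   initialized from quantile means (200 iterations, tolerance 1e-8 on the
   weighted log-likelihood, sigma floor 0.5 levels against spike collapse);
2. the deviation signal (empirical minus dominant fit) is split into its
   positive and absolute negative parts, each fitted by a small EM mixture.
   Deviation sigmas are capped at the dominant components' scale: the
   subordinate components exist to correct local mode shape, and
   unconstrained widths let them act as global bias terms on the class
   densities, destabilizing the decision threshold;
3. all signed weights are jointly refined by coordinate-wise proportional
   line search minimizing the L1 distance between the clipped, renormalized
   total density and the empirical one.  Only improving steps are accepted,
   so the recorded L1 trace is non-increasing and the final model is never
   worse than the dominant-only fit.  Components with |weight| < 1e-4 are
   pruned.

Each deviation component is then assigned to the nearer dominant mode,
giving two conditional class densities (dark / light) and class priors from
the clipped class masses.  The binarization threshold is the
Bayes-error-minimizing cut under the fitted model, searched over all Q
candidate levels; when the minimum is flat (well-separated classes leave a
zero-density gap, e.g. on noise-free synthetic data) the middle of the
tying range is taken.  On smooth fits this coincides with the level where
the class posteriors cross; on spiky histograms the posterior-crossing rule
itself is ill-posed (both densities underflow between the modes), which is
why the error-minimizing form is used.  `binarize` thresholds at this
level, which is equivalent to the voxel-wise posterior rule.

## Tissue extraction

Both tissue classes are bright in exactly one contrast, so the FS + WS sum
is bright everywhere inside the thigh: its LCDG light class, largest
26-connected component, holes filled slice-wise, is the whole-thigh mask.
The FS + WS histogram is taken over the full volume (the thigh is not yet
known); subsequent FS and WS fits are restricted to the thigh mask.

Bone is recovered geometrically: the dark component strictly enclosed by
the thigh (not touching its in-plane boundary; the slab's end slices do not
count as boundary) is the cortical shell, the cavity it encloses is marrow,
and their union is closed with a 3-voxel ball (after padding, so the
closing cannot erode at the slab ends).  Total muscle is the FS light class
within the thigh minus bone.  Fat is the WS light class within the thigh
*after bone removal* — marrow is bright on WS and would otherwise be
counted as intermuscular fat.  The fascia proxy separating subcutaneous
from intermuscular fat is the slice-wise convex envelope of the muscle mask
computed over voxel centers (so a digitized convex region maps onto
itself): fat inside the envelope is IMAT, outside is SAT.  Minimum
component size 1000 voxels rejects speckle.

## Registration (B-spline FFD)

Atlas volumes are aligned to the target by a free-form deformation: a
control-point lattice (one boundary ring beyond the volume) carries
displacement vectors, expanded to a dense per-voxel field by tensor-product
cubic B-splines.  The dissimilarity is the mean absolute intensity
difference between the target and the trilinearly warped source.

The optimizer is deterministic discrete ICM over control points with a
first-order smoothness penalty λ·Σ‖Δζi − Δζj‖ over the six grid neighbors
(λ = 0.1), run coarse-to-fine on a ×4 / ×2 / ×1 image pyramid with control
spacing 8 voxels at each level (an effective 32 → 16 → 8 full-resolution
spacing).  Candidate moves are axis-separable steps (±4, ±2 at the coarsest
level down to ±1 at the finest) rather than a full 3-D cross product of
displacements; under ICM the separable set explores the same optimum
structure at a fraction of the cost.  Local candidate energies use
B-spline-weighted SAD over the central two support cells of the moving
control point (the weight outside is ≤ ~1% of the basis mass); accepted
moves update the dense field over the full four-cell support.  A
center-of-mass translation pre-aligns the pair, and the returned field is
never worse (in SAD) than the identity.  Labels are transported
nearest-neighbor.

Atlas selection uses the mean slice-wise 2-D Pearson correlation between
rescaled intensities (within the thigh-mask union when available); an atlas
is kept when the mean correlation is ≥ 0.5.  A zero-variance slice
contributes r = 0.

## Shape prior, spatial model, and fusion

The shape prior is a voxel-wise Laplace-smoothed vote count over the warped
atlas label maps: p(l) = (votes_l + α) / (n + αL) with α = 0.5 inside the
target's muscle mask; outside, background has probability 1.  α keeps the
map-level product finite and deliberately caps the prior's per-voxel
log-odds (ln 11 with five unanimous atlases) so the other factors can
override a unanimous-but-wrong vote.

The spatial model is a Potts MGRF on the 26-neighborhood with bi-valued
potentials v_eq = −v_ne estimated analytically as 2·f_eq − 1, where f_eq is
the fraction of equal-label unordered neighbor pairs; pairs crossing the
domain boundary are excluded, and the same exclusion applies to the
neighbor counts in the conditionals (otherwise the background label creeps
inward from the mask edge).  The partition function is never evaluated —
only voxel-wise conditionals are needed, and those require local
normalization only.

Segmentation maximizes the product of shape, spatial and per-compartment
intensity probabilities (configurable exponents, default 1/1/1) by
sequential ICM in raster order.  The initial map is the per-voxel argmax of
prior × intensity inside the muscle mask.  Each sweep re-estimates the
Potts potential from the current map and re-fits each compartment's LCDG
intensity density (falling back to the previous sweep's density when a
compartment has too few voxels); sweeps stop when fewer than 1e-4 of the
masked voxels change or after 20 sweeps.  Ties go to the lowest label id.
Under frozen models the joint log-score (unary terms plus each pairwise
potential counted once) is non-decreasing per sweep — the usual ICM
guarantee.  IMAT voxels are excluded from compartment labels (compartments
are muscle tissue only); an optional post-step assigns each IMAT voxel to
its nearest compartment for volume-with-IMAT reporting.

A property of this model worth knowing: on a smooth muscle map the
estimated potential saturates (v_eq ≈ 0.95), so a two-neighbor majority
(spatial log-odds ≈ 3.8) outweighs even a unanimous atlas vote (ln 11 ≈
2.4).  MAP refinement therefore smooths high-curvature boundary detail.
When the initial map is already nearly exact — as on the phantom, where
registration residuals are sub-voxel — refinement trades a few tenths of a
percent of Dice at sector junctions for noise robustness; when the initial
map carries voxel-level errors (the regime the model targets), the same
mechanism removes them.

## Metrics

Dice = 2TP/(FP + 2TP + FN), precision TP/(TP+FP), recall TP/(TP+FN) from
voxel confusion counts over the full grid.  The Hausdorff distance is the
symmetric max-min Euclidean distance between boundary voxel sets (positive
voxels with a 6-neighbor negative or on the grid edge), in physical mm via
the voxel spacing.  Degenerate conventions: both masks empty → Dice 1, HD 0
with a warning; exactly one empty → Dice 0, HD is an error.  Volumes are
voxel count × dx·dy·dz, reported in mm³ and mL.

## Synthetic phantom

The phantom emulates a mid-thigh axial slab on a 96 × 96 × 50 grid at
1.5 mm isotropic voxels (the acquisition voxel size and a 50-slice slab, at
desk scale in-plane): background, a 10 mm SAT ring at 60 mm thigh radius, a
muscle annulus crossed by six thin (3 mm) radial IMAT streaks kept 4.5 mm
clear of bone and fascia, a cortical shell (12 mm) around a marrow core
(7 mm), and three 120° compartment sectors.  Noise-free intensities on a
0–255 scale: FS muscle 190 / fat 60 / cortical 20 / marrow 180 /
background 5; WS swaps muscle and fat, marrow stays bright and cortical
dark in both contrasts.  Gaussian noise is parameterized as a fraction of
the dynamic range.  An atlas family applies independent smooth random
B-spline warps (control spacing 16 voxels, uniform amplitudes up to the
jitter scale) to the shared topology; intensities are rendered *after*
nearest-neighbor warping of the tissue-code map, so truth and image are
always consistent.

What the phantom does not emulate: anatomically realistic compartment
shapes, MR bias fields, partial-volume mixing, within-muscle fat
infiltration, or genuinely independent inter-subject anatomy (family
members are warps of one topology).  Passing tests therefore demonstrate
the correctness and stability of the estimators and the pipeline's
composition — not clinical-grade accuracy on real MRI, for which the
contrasts are noisier, the fascia is not convex, and inter-subject
variability exceeds a smooth warp.

## Problem sizes and determinism

All randomness flows through explicit seeds; two runs with identical inputs
and configuration produce bit-identical outputs (sequential raster ICM, no
threading).  The test suite exercises the default 96 × 96 × 50 phantom:
tissue extraction at 0% and 5% noise, registration recovery of a known
≤ 4-voxel warp, and full leave-one-out over a 6-member atlas family with
3 mm jitter.  The acceptance script repeats these end-to-end measurements
with 3 of the 6 folds, 20 threshold-recovery draws of 1e5 samples, and a
20³ Potts estimate — sizes chosen so a complete from-scratch run stays in
the minutes range on one CPU.
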