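# Methods

This note documents the statistical procedures implemented in `vbmlearn`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about behavior on real data.

## The pipeline

The package analyzes two-group cohorts of smoothed, modulated tissue maps —
the per-voxel gray-/white-matter volume images produced by voxel-based
morphometry (VBM) preprocessing. Preprocessing itself (normalization,
segmentation, modulation) is out of scope; the pipeline starts from
per-subject 3D volumes on a common grid. The canonical cohort size it
targets is 34 + 34 subjects, matching typical single-site psychiatric
imaging studies.

### Coarse screen: voxelwise t with cluster extent

At each voxel the pooled-variance two-sample t statistic with
df = N₁ + N₂ − 2 is computed and converted to a two-sided p-value. Voxels
with p < α are kept only when they belong to a 3D connected component of at
least `min_cluster` supra-threshold voxels.

Choices:

- **Sidedness.** Two-sided tests, because both tissue increases and
  decreases are of interest; a screening criterion stated as "p < 0.05"
  without sidedness is interpreted symmetrically.
- **Connectivity.** Default 26-neighborhood (faces, edges and corners);
  6 and 18 are configurable and recorded in the output metadata. The choice
  affects cluster merging but not the per-voxel statistics.
- **No multiplicity correction by default.** Raw-p thresholding plus a
  cluster-extent filter is the convention this screen follows; a
  `bonferroni` flag divides α by the voxel count for users who want strict
  familywise control.
- **Zero-variance voxels.** If both group variances are zero, T is defined
  as 0 (p = 1) when the means agree and ±∞ (p = 0) otherwise, and the voxel
  is flagged. Equal-mean constant voxels therefore never survive.
- **Monotonicity.** For fixed `min_cluster`, the surviving set shrinks as α
  tightens: the stricter supra-threshold set is a subset of the looser one,
  so each stricter cluster lies inside a looser cluster whose size is at
  least as large and which therefore also passes the extent filter. The test
  suite asserts this on simulated cohorts.

### Fine selection: SVM-RFE

A soft-margin linear SVM (penalty C, default 1.0) is fit on the surviving
voxels; primal weights are recovered from the dual solution as
ω = Σ αᵢyᵢxᵢ, features are ranked by ωᵢ², and the lowest-ranked batch is
removed; the loop refits on the shrunken set.

Choices:

- **Batch size.** `ceil(elim_fraction × |F|)` of the *current* feature set
  (default 5%), minimum one feature. Applying the fraction to the shrinking
  set rather than the original count follows the recursive structure of the
  algorithm — each round operates on the set it inherited.
- **Stopping.** Elimination stops at exactly `ceil(retain_fraction × n)`
  features; the final batch is truncated to land on that size. Retention
  defaults to 40% (a value commonly tuned for gray matter; 14% is typical
  for white matter); both are exposed as free parameters with no claim of
  optimality.
- **Ties** in ωᵢ² are broken by ascending column index (stable sort), so
  rankings are reproducible.
- **Slack convention.** The hinge slack ζᵢ = max(0, 1 − yᵢ(ωᵀxᵢ + b)) is
  used, as in any standard soft-margin solver; a formulation that fixes
  ζᵢ = 1 − yᵢ(ωᵀxᵢ + b) as an equality would contradict ζᵢ ≥ 0 for
  well-classified points.
- **No standardization by default** — smoothed tissue maps are already on a
  common scale; an optional flag z-scores features using training-set
  statistics only.
- **Scale behavior.** Multiplying all features by s > 0 while rescaling the
  penalty to C/s² leaves the elimination order unchanged (the solutions map
  onto each other with ω → ω/s); the suite checks this on a small instance.

The solver behind each fit is libsvm via scikit-learn; the ranking loop, the
schedule and the dual-to-primal bookkeeping are implemented here and checked
against a one-at-a-time refit oracle and scikit-learn's own RFE on toys.

### Evaluation: leave-one-out with proportion-based metrics

Confusion entries are per-class rates (TP = N₁/N, TN = M₁/M, FN = 1 − TP,
FP = 1 − TN), which makes SN = TP, SP = TN, ACC = (SN + SP)/2 and
GM = √(SN·SP) algebraic identities. DM (Dice) and F2M are harmonic means of
sensitivity and precision with equal and sensitivity-heavy weights
respectively, set to 0 by continuity when TP = 0. AUC is the Mann–Whitney
probability with ties counted ½, computed from the pooled held-out decision
scores (one ROC per run, not per fold).

Two protocols:

- **nested** (default): screening and RFE are recomputed on each fold's
  training subjects. No statistic ever sees the held-out subject; the suite
  asserts this by corrupting a held-out row and checking the selection is
  unchanged. This is the honest generalization estimate.
- **pooled**: selection once on all subjects, SVM refit per fold. This is
  how many published pipelines appear to operate; it leaks selection
  information and overestimates accuracy, which is why both modes exist and
  every output is labeled with its mode.

A fold whose training screen yields no surviving voxel is recorded as a
failure: the held-out subject receives the training majority-class label
(ties go to the −1 class) and a decision score of 0, keeping LOO totals
well-defined.

### Region report

Connected clusters of the retained-voxel mask at or above the extent
threshold are reported in descending size order with: voxel count, the
world-space (mm) coordinate of the peak-|T| voxel (ties broken by lowest
linear index — the peak convention had to be fixed somewhere, and max |T|
is the natural choice for a t-screened map), and, when an integer atlas on
the same grid is supplied, the majority label plus the full per-label voxel
histogram (majority alone can hide clusters straddling a boundary). Reports
are invariant under atlas relabeling up to the corresponding permutation.

## The synthetic-cohort generator

Each subject volume is `baseline + subject offset + voxel noise`, with
spherical blob effects added to group-1 subjects *before* Gaussian smoothing
(so planted regions acquire the smooth boundaries real VBM effects have),
then smoothed at a stated FWHM (σ = FWHM/(2√(2 ln 2)) mm per axis,
reflect boundary). Defaults emulate the target study scale: 34 + 34
subjects, 6 mm FWHM, baseline 1.0 in unit-free tissue intensity (modulated
maps carry no canonical scale), between-subject s.d. 0.05, voxel noise
s.d. 0.1. All randomness flows from a single integer seed;
identical specs give bit-identical cohorts.

The synthetic atlas partitions the grid into `n_regions` rectangular parcels
by recursive coordinate bisection (longest axis, proportional split), which
guarantees a deterministic, exhaustive, nonempty partition; the seed only
permutes label identities.

What the generator does **not** emulate: registration error, segmentation
artifacts, spatially varying noise, age/sex covariates, site effects, or
anatomically shaped (non-spherical) effects. Passing recovery tests
therefore establishes that the implementation is correct under its stated
model — not that the pipeline attains any particular accuracy on real
MRI cohorts.

## Verification problem sizes

The test suite runs the full pipeline at desk scale, chosen as the smallest
sizes at which each property is statistically meaningful:

- signal recovery: one 34 + 34 cohort on a 16³ grid (2 mm voxels, 6 mm
  FWHM) with a radius-3 blob (123 voxels, above the 50-voxel extent
  threshold) of effect 0.5 against 0.1 voxel noise — the strong-effect
  regime; screening recall, RFE enrichment over size-matched random subsets
  (100 seeds on 10³ grids), and nested-LOO accuracy are all asserted there;
- null calibration: 20 seeds of independent-noise cohorts (no smoothing, no
  subject offset) for the rejection rate at α, and 20 seeds of 17 + 17
  null cohorts for nested-LOO accuracy against its own sampling error;
- oracle equivalence: 1000-voxel t-map vs. a textbook implementation,
  50 random 8³ masks vs. flood fill, 10-feature RFE toys vs. one-at-a-time
  elimination, 100 score sets vs. exhaustive pair counting.

## Known limitations

- Linear kernels and two classes only; no covariate adjustment.
- Screening and RFE assume a common grid; no resampling between spaces.
- The pooled evaluation mode is intentionally optimistic and should never
  be quoted as a generalization estimate.
- LOO on small cohorts has high variance; accuracies from 68 subjects carry
  sampling error of several percentage points regardless of protocol.
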