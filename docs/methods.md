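# Methods

## Geometry and data model

All volumes live on an isotropic grid (default 0.8 mm) with fixed axis
semantics: x left→right, y posterior→anterior, z caudal→rostral. NIfTI
images are reoriented to the closest RAS-like layout on read, so index
arithmetic is layout-independent. Voxel indices are 0-based; extents are
inclusive slabs, `(max − min + 1) · voxel_size`, so a single-voxel mask has
extent equal to one voxel size — this convention makes a 16-slice mask at
0.8 mm exactly 12.8 mm and a 333-voxel mask exactly 170.496 ≈ 171 mm³.
Mask membership is any nonzero value; no probabilistic thresholding.

The literature is not consistent about which axis label carries the
rostrocaudal direction; we standardize on z (axial slice stacking) and the
rostral/caudal split is always "either side of the median voxel z".

## Contrast-ratio extraction

CR = (S_LC − S_ref)/S_ref, dimensionless and invariant to global intensity
rescaling. One reference summary per subject normalizes every regional CR
(whole, rostral, caudal, left, right × mean/median/max): regional CRs from
per-region references would not be comparable across regions.

The reference patch is a single-slice square, `patch_width_voxels` (default
10 ≙ 8 mm at 0.8 mm) on a side, centered in x at the midpoint of the
per-side LC centroids (rounded to the nearest voxel), on the floor-midpoint
slice of the mask's z-range, displaced `offset_voxels_anterior` voxels
(default 5) beyond the mask's anterior face. The nominal "5 voxels (2 mm)"
description in the imaging literature is internally inconsistent at 0.8 mm;
the voxel count is taken as authoritative because it is what an automated
placement can apply exactly. A bilateral 3-D mode places two mirrored
cuboids totalling 144 voxels anterior to each LC. Placement never
intersects the LC mask and fails loudly when the grid lacks anterior
padding.

Rostral/caudal: median of member-voxel z-coordinates; ties (z = median) go
caudal, making the partition deterministic and exhaustive. Left/right:
26-connected components when exactly two exist, assigned by centroid x
under a configurable convention (neurological default: larger x = subject
right); otherwise a mid-x plane fallback. Percentage overlap between masks
is measured relative to the second argument, |a∩b|/|b|; the per-rater
agreement of a conjunction is |∩|/|rater| and Dice 2|∩|/(|r1|+|r2|).

QC: a subject with negative whole-LC mean CR is excluded
(motion-corrupted); externally supplied motion flags are honored first so a
doubly flagged subject is counted once.

## Synthetic phantom

The generator emulates the cohort features the pipeline must cope with, not
MR physics:

* **Trajectory.** CR(age) rises as `cr_at_peak + curvature·(age − peak)²`
  to a peak (default 0.094 at 60 y, curvature −2·10⁻⁵/y²) and continues
  linearly after it: rostral at −8·10⁻⁴ CR/y, caudal flat. The piecewise
  form (rather than a global quadratic) gives the two-lines test a true
  positive (rostral) and a true negative (caudal plateau) case.
* **Raw signal.** Pontine background 1000 a.u. + (−0.5 a.u./y)·age +
  80 a.u. for the 50 ms TR group + a per-subject level (SD 30 a.u.). The
  between-subject term keeps the pons–age association weak and the
  covariate VIFs near realistic magnitudes (age ≈ 1.1, reference ≈ 3)
  instead of degenerate collinearity. LC tubes sit at background·(1+CR)
  with independent voxel noise (SD 5 a.u.).
* **Geometry.** Two parallel tubes, 16 z-slices, 11 (left) + 10 (right)
  in-plane voxels per slice — 336 voxels, 12.8 mm slab, left > right as in
  published consensus masks. Per-subject variability removes outer "fringe"
  voxels with probability 0.1, giving an age-independent voxel-count spread
  without touching the tube cores.
* **Noise and exclusions.** One CR deviation per subject (shared by both
  regions, SD interpolated 0.018→0.026 between the age-range endpoints)
  reproduces age-increasing between-subject variance. Ages are uniform over
  18–88 (the source cohort's age histogram is unpublished). Motion corrupts
  an exact `round(motion_fraction·n)` subset (default fraction 18/623, so
  QC retains 97%): in-plane smearing plus attenuation of LC voxels below
  background, which drives the mean CR negative at default severity.
  Exact counting keeps the retained percentage stable across seeds.

All randomness flows from one integer seed through a `SeedSequence` spawn
tree; identical seeds give bit-identical cohorts, tables and volumes.
Passing tests on the phantom demonstrate correct plumbing and the intended
operating characteristics of the statistics under known ground truth; they
do not certify performance on real data, which has partial-volume effects,
registration error, bias fields and non-uniform age sampling that the
phantom deliberately omits.

## Trajectory statistics

**OLS and AIC.** Fits go through statsmodels OLS on explicit design
columns. AIC is `2k − 2 log L` with the full Gaussian log-likelihood
(2π constants included) and k counting the intercept, slopes and the
residual variance. Only AIC differences between models of the same response
are meaningful, and those are convention-invariant; fixing the convention
makes reported differences reproducible. Exact fits are flagged degenerate
rather than rejected; rank-deficient designs raise with the names of the
collinear columns.

**Two-lines test.** An inverted U is accepted only when two unconstrained
regression segments on either side of a breakpoint both have individually
significant slopes (α = 0.05) of opposite sign. Without a supplied
breakpoint, the quadratic vertex x* = −b₁/(2b₂) is located with a
delta-method standard error, then a single "Robin Hood" reallocation step
moves the breakpoint within ±1 SE toward the stronger arm, in proportion to
the imbalance of the two slope |z|-scores, handing observations to the
weaker arm. We deliberately do **not** search over many candidate
breakpoints for the one maximizing the weaker |z|: in simulation that
best-of-many selection inflates the "significant decline" rate on
plateau-shaped data to 10–35%, whereas the single reallocation step keeps
it near the nominal 5% while preserving essentially full power on true
U-shapes (measured on phantom cohorts at n ≈ 600). A vertex outside (or at
the very edge of) the observed x-range short-circuits to a *monotonic*
verdict. Subgroup analyses (old vs young comparisons, the variance ratio)
use this breakpoint unless a fixed age is supplied.

**JZS Bayes factor.** For an independent-samples t with group sizes n₁, n₂
and effective size N = n₁n₂/(n₁+n₂), ν = n₁+n₂−2, BF₁₀ integrates the
t-likelihood over the effect-size scale g (Cauchy prior scale r = √2/2 by
default, inverse-chi-square weight on g), divided by the point-null
likelihood. The integral is evaluated with adaptive quadrature after the
transform g = u/(1−u) maps (0, ∞) to (0, 1) — the transformed integrand is
bounded — at relative tolerance 1e-10, with a convergence guard. The
implementation agrees with an independent 10⁶-node brute-force quadrature
and with pingouin to ≲1e-6 relative.

**Effect size.** d = t·√(1/n₁+1/n₂) with the normal-approximation
SE² = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂)) and a ±1.96·SE interval; this
reproduces printed 2-decimal CIs exactly. Variance comparison is the plain
two-sided F ratio (older/younger). VIF regresses each predictor on the
others with an intercept; ≥ numerically perfect collinearity reports ∞.

## Problem sizes and numerical choices

Phantom-based statistical properties are evaluated on 605-subject cohorts
(the analyzed-sample size) over 20 seeds for recovery/power checks, and 500
replications of n = 200 for null calibration of the two-lines verdict; the
default grid is 48×48×32 voxels, ample for the tube geometry plus reference
placement. Quadrature tolerance 1e-10 (JZS); OLS agreement with the normal-
equations oracle is asserted at 1e-8; noise-free extraction identity at
1e-12.

## Known limitations

* The phantom's tubes are axis-aligned rectangles, not curved nuclei; no
  partial-volume modelling, bias fields or registration error.
* Visual motion QC cannot be automated; only the negative-CR rule is. Motion
  flags must be supplied (or simulated) for the rest.
* The two-lines breakpoint refinement is one defensible choice among
  several published variants; a fixed breakpoint can be supplied to bypass
  it.
* Bayes factors are provided for two-sample comparisons only, not for
  regression model comparisons.
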