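# Methods

This note documents the models behind `subfrax`, the parameters that matter,
and the numerical choices a maintainer would want to know about. Everything
stated here is computed by the test suite or `scripts/acceptance.py`; no
empirical claim goes beyond what those runs show.

## Spatial frame and conventions

All objects live on one rectilinear grid (`ImageGrid`), default 96³ voxels
at 2 mm isotropic spacing (19.2 cm field of view) with the origin centered
on the prostate centroid. Axes are fixed package-wide: axis 0 = left–right,
axis 1 = anterior–posterior (positive = posterior), axis 2 =
inferior–superior (positive = superior). The 2 mm default resolves the
2–4 mm clinical margins with at least one voxel while keeping every
pipeline stage interactive; spacing is configurable.

Membership of a voxel in a structure is decided at its center, and every
voxel contributes its full volume — no partial-volume weighting anywhere.
This makes every metric reproducible by a brute-force sort/count oracle,
which the test suite exploits. NIfTI I/O writes diagonal affines in this
frame; axis-aligned files in other orientations are reoriented on load and
oblique affines are rejected.

All randomness flows from integer seeds through `numpy.random.SeedSequence`
spawning (cohort → patient → fraction → phase), so cohorts are bit-for-bit
reproducible and per-fraction draws are independent.

## Synthetic anatomy

Phantoms are analytic shapes rasterized at voxel centers: a prostate
ellipsoid (semi-axes 20/18/22 mm LR/AP/SI), a 6 mm-radius spherical GTV
fully inside it, a bladder ellipsoid superior-anterior, a curved rectal
tube posterior, a sphincter disc inferior, and an elliptic body cylinder.
Organ shells are carved disjoint with fixed priority prostate > bladder >
rectum > sphincter (the carving rule is a package convention; input
contours in clinical systems are simply accepted as drawn). Bladder and
rectum abut the prostate, as in the male pelvis, so the OARs sit inside the
dose gradient and their constraints are genuinely exercised.

Cohorts jitter sizes (multiplicative, SD 8 %) and offsets (additive, SD
2 mm) per patient; draws violating GTV-in-prostate containment are redrawn.
Analytic shapes give exact ground truth: the rasterized prostate volume is
checked against the ellipsoid formula, and dilation/distance oracles are
enumerable. The phantom dimensions are literature-typical defaults, not fit
to any cohort; patient-specific realism (lesion shape, rectal gas, bone) is
out of scope, so passing tests demonstrate correctness of the evaluation
machinery, not anatomical fidelity.

## Intrafraction motion model

Each PV phase draws a forward displacement field PRE → PV as a sum of:

1. **Rigid drift.** The 3D translation magnitude follows a folded normal
   |N(μ, σ)| with (μ, σ) solved (Brent root-finding on the folded-normal
   moment equations) so the sample mean/SD equal configured targets —
   defaults 3.0 ± 2.2 mm (PV1) and 3.5 ± 2.0 mm (PV2). Only mean and SD are
   matched; percentiles of the clinical drift distribution are not asserted.
   Direction is an anisotropically weighted random unit vector, weights
   (0.5, 1.0, 1.0) on (LR, AP, SI), reflecting the AP/SI dominance of
   bladder- and gas-driven prostate motion. Rotations are N(0, sd) per axis
   (default sd 1.5°), applied LR→AP→SI about the prostate centroid and
   capped at ±45°. The rotation arm is clamped at the taper inner radius:
   a prostate rotation shears nearby soft tissue but must not swing tissue
   10 cm away on a rigid lever. The whole rigid component is multiplied by
   a smoothstep taper (1 inside 50 mm from the prostate centroid, 0 beyond
   110 mm) so a "global" prostate drift leaves the body outline in place;
   the wide band keeps the field gradient small enough for stable numerical
   inversion even at the large rotations used in the outlier study.
2. **Smooth deformation.** White noise convolved with a Gaussian kernel of
   the configured correlation length (default 25 mm), scaled to a configured
   RMS magnitude (default 1.5 mm). The noise is drawn on a lattice coarsened
   to ~¼ of the correlation length, smoothed there and trilinearly
   upsampled — the field has no spectral content below that scale, so this
   is the same model at a fraction of the cost.
3. **Optional bladder filling.** A radial Gaussian-windowed expansion about
   the bladder centroid, parameterized by its peak displacement (default
   off).

The rigid component is returned separately as ground truth. Fields are
forward maps; masks are propagated by pull-back through the numerically
inverted field (damped fixed-point iteration, tolerance 0.05 mm, max 50
iterations, run in float32 whose ~10⁻³ mm rounding is irrelevant at that
tolerance), with trilinear interpolation of the indicator thresholded at
0.5. A coarse Jacobian bound rejects clearly folding fields; anything that
passes the bound but fails the fixed-point tolerance is rejected by the
inversion itself with the residual in the message.

## Registration (the ATP computation)

The plan adaptation uses a translation-only registration of the prostate
mask (target alignment, as clinically intended; no grayscale images exist
in this pipeline). The integer stage maximizes mask overlap — equivalently
Dice, since mask sizes are constant — over all voxel offsets within the
search radius (default 15 mm), evaluated simultaneously by FFT
cross-correlation on the union bounding box; the correlation is rounded
back to exact integer counts so the tie-breaking (smaller shift norm, then
lexicographic) is deterministic. An optimum whose full 3×3×3 neighbourhood
is not inside the searched ball raises an error advising a larger radius.

The optional sub-voxel stage fits a parabola per axis through the overlap
profile at the optimum ±1 voxel. Mask-overlap profiles are triangular, not
parabolic, near the peak — a profile A − c·|j − f| puts the parabola vertex
at f/(2(1−f)) — so the vertex estimate is inverted through that map. Over
random oblique sub-voxel shifts the mean recovery error is ≈0.35 mm; a
purely axis-aligned sub-voxel shift of the symmetric prostate rasterizes to
an exact voxel roll, in which case no estimator can beat nearest-voxel
(≤1 mm error). Rotation and deformation leak into the translation estimate;
the workflow records the resulting discrepancy against the rigid ground
truth rather than suppressing it.

## Dose model

The daily (ATS) plan is a deterministic analytic surrogate for the
treatment planning system: the PTV is grown by a flash margin (default
1.65 × penumbra σ), the grown indicator is convolved with an isotropic
Gaussian kernel (σ default 4 mm), multiplied by the full-scheme
prescription (3625 cGy = 5 × 725) and rescaled by one global factor so the
fraction of PTV voxels at or above the V95 reference dose
(round(0.95 × prescription) = 3444 cGy) first reaches 99.5 %. The flash
margin places the ~95 % isodose at the PTV surface — as conformal plans do —
so the interior plateau sits near the prescription (~104 % here) instead of
several times it, and OAR doses land in a clinically sensible range. This
surrogate preserves the only properties the analysis needs: a conformal
dose with realistic fall-off that moves rigidly under the isocenter shift.
Beams, fluence, MLC and tissue heterogeneity are out of scope.

The ATP isocenter shift translates the dose grid by spline resampling
(default cubic, exact on whole-voxel shifts; trilinear available). Optional
multiplicative voxel noise (N(1, 0.03) emulating a Monte Carlo statistical
uncertainty) is off by default so every run is deterministic.

Dose is expressed at full-scheme scale throughout and each sub-fraction
delivers one tenth of it; sub-fractions are assessed against the
full-scheme constraint table, which is what the cGy limits require.

## DVH metrics

V_D is the inclusive percentage of structure voxels with dose ≥ D. D_cc
sorts the structure voxels hottest-first, accumulates voxel volumes, and
linearly interpolates between the voxels bracketing the requested volume;
querying more volume than the structure has returns its minimum dose with a
warning. D_mean is the arithmetic mean. The cumulative DVH curve evaluates
V_D on uniform bin edges and therefore agrees with `v_dose` exactly at
those edges. Inclusive thresholds and interpolated D_cc are documented
choices; the voxel-counting convention makes all three metrics equal to
their brute-force oracles to float precision.

## Margin recipe

`expand_margin` implements ellipsoidal dilation in world millimetres: a
voxel center p is included iff min over mask voxel centers q of
√(Σ((p−q)ᵢ/mᵢ)²) ≤ 1, computed with an exact Euclidean distance transform
on margin-scaled spacings (a 10⁻⁹ slack keeps offsets lying exactly on the
ellipsoid inside under float rounding; zero-margin axes degenerate to no
growth). Exclusion structures are subtracted *after* expansion — "staying
outside" constrains membership, not growth paths; whether the clinical
system instead blocks growth geodesically cannot be determined, and the
subtractive reading is the documented choice. The PTV is expanded without
OAR carving, also a documented, configurable choice. The recipe asserts
gtv ⊆ ctv, prostate ⊆ ctv ⊆ ptv and is idempotent.

## Workflow and evaluation

Per fraction: plan on PTV_PRE → score on PRE contours (ATS case); sample
PRE→PV1 motion, register, shift the dose, score approved and corrected;
independently sample the cumulative PRE→PV2 motion and repeat. The second
sub-fraction reuses the shifted ATS plan (no re-optimization between
sub-fractions), and the PV2 registration is PRE↔PV2, matching how the
cumulative drift is defined. Corrected targets are re-created from the
warped prostate/GTV by the margin recipe; corrected OARs are warped, not
re-created. Dose is not recomputed on the deformed anatomy — with a
near-homogeneous pelvis the shifted dose field is the delivered dose to
good approximation, and dose recomputation is out of scope.

The approved case is scored in the plan frame: a rigid shift applied to
dose and contours together leaves every dose-volume metric unchanged, so
the unshifted pair is evaluated directly. This is exact. The alternative
"room frame" reading (resample both onto the grid after shifting) is
retained as an option; it differs only through voxelization, which is worth
quantifying: re-rasterizing a sub-voxel-shifted mask relocates boundary
voxels into the dose fall-off and can erode PTV V95 by 1–8 % at 2 mm
spacing while leaving CTV V95 untouched. Corrected cases necessarily
involve such resampling (the anatomy really moved), so their PTV drops
contain a voxelization component on top of the true deformation effect;
CTV-based conclusions are insensitive to it.

Constraint evaluation reports strict and with-tolerance passes (tolerances
applied in the permissive direction: CTV floor 98.9 %, PTV floor 96 %).
Cohort summaries give per-case V95 mean ± SD, with-tolerance pass rates,
and mean approved-minus-corrected drops computed on paired sub-fractions
only.

## Problem sizes and experiments

The packaged experiments (`subfrax.experiments`, also run by
`scripts/acceptance.py` and the test suite) use: 100 random (dose, mask)
instances on 24³ grids for the DVH oracles; six blobs × two margin sets on
24³ grids for the O(N²) dilation oracle (exact agreement required in both);
100 + 100 registration recovery cases; 10 000 drift draws per phase for the
calibration self-check (0.1 mm tolerance on mean and SD); 50 pure-translation
fractions for the translation-covariance study (CTV V95 within 0.5 % of ATS);
and 20 draws at 8 mm RMS deformation / 10° rotation SD for the
outlier-mechanism study (at least one sub-fraction must fail the corrected
CTV floor while passing the approved evaluation). The acceptance script runs
a 6-patient × 3-fraction cohort — the statistics it reports are cohort means
and rates whose estimators are identical at larger cohort sizes; the full
15 × 5 default runs in a few minutes via `subfrax run` or `run_cohort`.

## Known limitations

* The motion model matches first and second moments of drift magnitude,
  not the full clinical distribution or its temporal structure (no cine
  dynamics, no gas pockets beyond smooth deformation).
* The dose surrogate has no beam structure and no OAR sparing: it is purely
  conformal to the flashed PTV. OAR dose levels therefore depend only on
  phantom geometry and penumbra width, and a jittered anatomy whose
  sphincter sits unusually close to the target can violate the sphincter
  mean-dose limit already at the daily plan — where a clinical optimizer
  would have traded coverage for sparing. Only the qualitative OAR
  behaviour (which case is hotter, whether constraints bind) is meaningful.
* PTV-coverage drops at 2 mm resolution include a mask-voxelization
  component of order 1 %; CTV coverage is robust to it.
* Sub-voxel registration accuracy is geometry-dependent and degenerates to
  nearest-voxel for perfectly symmetric, axis-aligned cases.
* Interfraction dose accumulation and the post-delivery validation scan
  are not modelled.
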