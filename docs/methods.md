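# Methods

This note documents the models, conventions and numerical choices behind
`petzones`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open design decisions were made.

## Imaging model

A PET volume is a regular 3D grid of non-negative, body-weight-normalised
SUVs with fixed `(x, y, z)` index order; `origin` is the physical position
(mm) of the centre of voxel `(0, 0, 0)` and voxel `(i, j, k)` sits at
`origin + index * spacing`.  Files are NIfTI-1 with a diagonal affine; no
orientation reinterpretation is attempted.  `suv_bodyweight` implements
`SUV = concentration [Bq/mL] × weight [g] / dose [Bq]` with inputs assumed
decay-corrected at injection — no decay term is applied.  Resampling is
trilinear for images; masks interpolate the 0/1 indicator trilinearly and
re-threshold at 0.5, with the outer physical edges of the grid aligned so
extent is preserved to within one voxel.

## Zones

Zone construction uses the baseline scan only (features are pre-treatment
predictors).  Thresholds are inclusive at the lower bound and exclusive at
the upper bound of the zone-2 band, so zone-1 `[0.45·SUVmax, ∞)` and
zone-2 `[0.20·SUVmax, 0.45·SUVmax)` partition exactly; zone-3 is the gland
minus zone-1 and deliberately *contains* zone-2.  All suprathreshold
voxels are kept by default (no connected-component filtering — the
simpler, reproducible rule); an optional flag restricts the relative
delineation to the component containing the SUVmax voxel.  Every zone
build asserts the five set relations (disjointness of zone-1 with zones
2/3, tiling of the gland by zones 1 and 3, containment of zone-2 in
zone-3, and the zone-1 SUV bound).

## The 119-feature vector

Eight categories with fixed cardinalities 18/12/14/24/14/16/16/5.
Intensities are discretized with a fixed bin *count* (default 64 equal-
width bins on the masked range; a fixed bin width is available and the
configuration is echoed into every output, since texture values are only
comparable under one discretization).  Matrices follow the widely used
reference conventions:

* GLCM and GLRLM over the 13 unique 3D directions at voxel distance 1,
  GLCM counted symmetrically; features evaluated per direction and
  averaged without weighting.
* GLSZM zones and GLDM dependencies use 26-connectivity; the GLDM
  dependence tolerance is zero (identical gray level only) and the
  dependence size of a voxel is 1 + its number of dependent neighbors.
* NGTDM neighborhood averages use the 26 in-mask neighbors; voxels
  without any in-mask neighbor are excluded from the table.
* Matrices are indexed by the distinct gray levels actually present, and
  the formulas weight rows by the level values; `Ng` in the normalised
  inverse-difference features is the number of distinct levels present.

Degenerate single-level regions follow a fixed convention instead of
producing NaN: correlation-type features (Correlation, MCC, imc1, imc2)
are 0, entropies are 0, and the inverse-difference family is 1.
Percentiles use linear interpolation between order statistics; skewness
and kurtosis are population moments with kurtosis on the Pearson
convention (normal → 3), both 0 for constant regions.

Shape features are mesh-based: marching cubes extracts the 0.5
iso-surface of the zero-padded mask indicator in physical coordinates,
mesh volume comes from signed tetrahedra and surface area from the
triangle sum; sphericity is `π^(1/3) (6V)^(2/3) / A`.  The indicator is
first smoothed with a narrow Gaussian (0.8 voxel per axis) so the surface
interpolates the underlying boundary rather than the voxel staircase:
meshing the raw indicator overestimates the area of any smooth object and
caps the sphericity of a finely voxelized ball near 0.92, whereas the
smoothed surface reaches 0.993 at radius 20 voxels.  The cost is that
sharp-edged objects are slightly rounded (a voxelized cube reads ~10%
above its closed-form sphericity); for anatomical masks the smooth-object
behaviour is the right trade.  Masks small or thin enough that smoothing
would sink them below the iso-level fall back to the raw indicator, so a
single voxel is meshed as its cube.  Axis lengths are `4·sqrt(eigenvalue)`
of the sample covariance of masked voxel centres; degenerate covariances
report zero lengths and Elongation/Flatness of 1.

The diagnostics category is defined here as twelve numbers: whole-image
SUV min/max/mean, mask voxel count, 26-connected component count and
masked SUV min/max/mean on the native grid, and voxel count plus masked
SUV min/max/mean on the resampled grid.  Resampling is off by default
(the interpolated block then repeats the native statistics, making
`diagnostics_Mask-interpolated_Minimum` simply the minimum SUV in the
mask — for zone-3, the gland floor outside the tumor); when enabled
(e.g. 2×2×2 mm) it feeds both the interpolated diagnostics and texture
extraction.

## Response model

Traditional parameters per patient: SUVmax is the maximum over lesions,
MTV (mL) and TL sum over lesions, SUVmean is the volume-weighted mean
TL/MTV — the only aggregation under which TL = SUVmean × MTV survives
summation.  The reduction ratio is `−(PET2 − PET1)/PET1 × 100%`; response
on a parameter requires strictly RR > 30 (a tie is a non-response).
Cohort tables report per-parameter responder counts and percentages, and
the across-parameter average percentage *truncated* to an integer — the
only convention consistent with the published tabulations this package is
designed to mirror.

## Screening

Each feature/zone/parameter cell compares responders against
non-responders.  Normality is gated by Shapiro–Wilk at α = 0.05 per
group; both groups normal → Welch (unequal-variance) t-test, otherwise
Mann–Whitney U (exact enumeration for combined n ≤ 16 without ties,
tie-corrected normal approximation with continuity correction otherwise).
Constant-in-both-groups data fall back to Mann–Whitney with a warning.
Significance is two-tailed p < 0.05 with **no multiplicity correction** —
a faithful-replication choice, not an endorsement; with 119 features ×
4 parameters the family-wise error is substantial, and the type-I
calibration test quantifies the per-test rate only.  Selection requires
significance on ≥ 3 of the 4 parameters; cross-zone consistency requires
≥ k significant parameters in every zone, with k = 1 by default because
the cross-zone surface-to-volume observation this mirrors showed 2
significant parameters per zone (both k = 1 and k = 2 reproduce it).

## Synthetic cohort

The generator emulates the study conditions: 35 patients, 73% responder
fraction, paired scans.  Each phantom is an ellipsoidal gland (semi-axes
25×20×20 mm, 2 mm isotropic voxels on a 64×64×48 grid) at background
SUV 1.2 with a quadratic cooling toward the rim, ambient 0.3 outside,
plus a focal tumor whose uptake decays as a Gaussian from a peak near
SUV 12 (per-patient lognormal jitter, sd 0.10).  The Gaussian width is
set so the 45% iso-surface sits at the configured tumor radius, making
zone volumes analytically checkable; the 20% iso-surface then guarantees
a non-empty zone-2.  A multiplicative lump field (Gaussian-filtered white
noise, 3 mm correlation length) roughens the uptake; additive Gaussian
noise (5% of background, truncated at zero) is applied last.  Defaults
are order-of-magnitude choices — no voxel-level patient data exists to
calibrate the noise texture against.

Group structure enters twice, independently, so screening power and
labeling are separately controllable:

* **Baseline differences** (what screening should find): responders get
  smaller (7 vs 10 mm radius), rougher (lump amplitude 0.35 vs 0.10)
  tumors and a cooler gland rim (rim cooling 0.45 vs 0.20).  These three
  mechanisms jointly orient all planted features: smaller tumors lower
  zone-1 mesh volume and the count-scaled non-uniformities (rln, dn),
  shrink the zone-2 shell (lower minor axis length) and raise zone-1/2
  surface-to-volume ratio while lowering it in zone-3 (a smaller cavity
  in the gland) and raising zone-3 sphericity; rougher texture lowers the
  inverse-difference homogeneities and imc1 while raising NGTDM contrast
  and the small-dependence emphasis; rim cooling lowers the zone-3
  interpolated minimum.
* **Dynamics**: true reduction-ratio targets are drawn per group (e.g.
  responders 40–60% for SUVmax, 40–65% for MTV; non-responders −5–15%),
  the follow-up scan scales the tumor peak by `1 − RR_SUVmax/100` and the
  iso-radius by `(1 − RR_MTV/100)^(1/3)`.  The lump pattern is spatially
  rescaled with the tumor (the follow-up lesion is an exact scaled copy)
  and a ≤ 3-step noiseless voxel-count correction refines the radius
  scale, so measured reduction ratios track their targets to within about
  5 percentage points including noise.  SUVmean tracks SUVmax (the
  profile shape is preserved) and TL compounds the two, so non-responder
  draws are capped so the compounded TL reduction stays below 30%.

The *null* configuration removes group structure everywhere: both groups
share one parameter set and every patient's reduction ratios are drawn
from a single wide range spanning the 30% threshold, so the four
labelings are informative about nothing and only weakly mutually
correlated — the appropriate negative control for the ≥3-of-4 selection
rule.

Everything is driven by `numpy` `SeedSequence` spawning, so a fixed
configuration and seed reproduce the cohort bit for bit.

### What the phantoms do and do not show

The generator reproduces the *logical* structure of the analysis —
threshold geometry, zone topology, feature directionality, label
arithmetic — not scanner physics.  There is no point-spread function,
reconstruction noise correlation, attenuation artefact, bladder uptake, or
anatomical boundary ambiguity.  Passing the end-to-end recovery test shows
the pipeline correctly propagates planted image-level differences through
zones, features, labels and statistics; it does not validate that real
ADT response produces such differences.  Planted effects also move
correlated neighbours of the named features (most of the GLCM family
moves with idmn), so the false-selection rate among non-planted features
is not a meaningful quantity for image-level planting; false-positive
control of the selection rule itself is tested at the feature-table level
and on null cohorts.

## Problem sizes in tests

The default test run uses the study-scale cohort (n = 35) for the
end-to-end recovery and null-control checks, 50 random phantoms for zone
invariants, 100 randomized ≤ 4×4×4 grids against the brute-force texture
oracle, and 500 replicates for type-I calibration — sizes chosen so the
whole suite completes in a couple of minutes on a laptop-class machine
while keeping the Monte-Carlo bounds meaningful.
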