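# Methods

This note records the models, the numerical choices, and what the phantom
experiments do and do not demonstrate.

## Phantom model

Subjects are rendered from a common labeled template: concentric ellipsoids
of white matter (WM), a gray-matter (GM) ribbon (default 4.5 mm ≈ 3 voxels),
a CSF shell, and background, on a 1.5-mm isotropic grid (default 48³–64³).
Default class intensities follow the qualitative contrast of the two
sequences — T1: CSF 0.20 < GM 0.45 < WM 0.75; FLAIR: CSF 0.10 (suppressed),
WM 0.50 < GM 0.60 — with nominal within-class SD 0.02 (arbitrary units).

**Deformations.** Each subject carries a smooth random displacement field
u (white vector noise smoothed to 8 mm, zero-meaned, RMS amplitude 2 mm by
default, rescaled by 0.7 until det(I+Du) > 0, i.e. diffeomorphic). The
stored field maps *template → native* coordinates, so "spatial
normalization" of a native image is a single forward interpolation at
y + u(y), and modulation by J = det(I+Du) satisfies the change-of-variables
identity ∫ M(y+u(y))·J(y) dy = ∫ M(x) dx exactly in the continuum. Native
rendering inverts the warp once by fixed-point iteration (20 sweeps,
adequate for 2-mm/8-mm fields). High-dimensional spatial normalization of
real anatomy is deliberately *not* modeled: subjects share the template's
topology and analyses run in template space with the known warp standing in
for the estimated one. Consequences: the modulation mathematics is exercised
exactly, but registration error — a major driver of false positives in real
VBM — is absent.

**Artifacts.** A multiplicative bias field exp(random polynomial, degree 2,
log-SD 0.05) and additive Gaussian noise (SD 0.02 per channel; Rician
optional) corrupt each channel. No cortical folding, no partial-volume
ramps, no MR sequence physics, no skull.

**Lesions.** A lesion is a sphere centered on the gray–white interface with
three independent effects: (1) *junction blurring* — interface-shell T1
intensities move toward the GM/WM midpoint by fraction `junction_blur`;
(2) *FLAIR hyperintensity* — GM∪WM voxels in the sphere gain
`flair_delta` × (WM FLAIR SD); (3) *thickening/thinning* — relabeling of
voxels adjacent to the ribbon by `thickness_factor`, with intensities
shifted by the class-mean difference so the noise realization is preserved.
Voxels outside the sphere are bit-identical to the input. No quantitative
FCD contrast is established in the literature at phantom scale, so effect
sizes are free parameters; the test suite sweeps them (blur 0.2–1.0, FLAIR
offset 1–5 SD) rather than fixing a single "realistic" value. Cohort
defaults (ages uniform 19–64, strong lesions blur 0.8–1.0 / 4–6 SD) define
the standard study conditions.

## Segmentation

A four-class Gaussian-mixture EM (background, CSF, GM, WM; diagonal
covariance over 1–2 channels) with variance floor 1e-8. Initialization:
k-means over 999 evenly spaced points spanning the robust T1 intensity
range (0.1–99.9 percentiles) — clustering the *support* rather than the
voxel mass keeps the dominant background mode from swallowing several
classes — then per-channel class means from the induced assignment. Class
identity is resolved after convergence by ranking bias-corrected T1 means
(removes EM label switching deterministically). Convergence: relative
log-likelihood change < 1e-6, max 60 iterations; non-convergence is logged,
not raised.

The bias field is a 3-D polynomial (total degree 3 by default) per channel,
refit every 4 EM iterations by least squares on the log-ratio of observed
to reconstructed intensity (voxels with near-zero expected intensity are
excluded; the log-field is zero-meaned, so the field is a pure shape
correction). Between refits the EM iterations monotonically increase the
observed-data log-likelihood (asserted in tests to 1e-8 relative); the
refit itself changes the corrected data, so monotonicity across refits is
not claimed. This is a prior-free segmentation: no warped tissue
probability maps, no spatial regularization — adequate for phantom
geometry, not for real heads with dura/vessels.

TIV = Σ(GM+WM+CSF probability) × voxel volume, in mL.

## Feature maps

Smoothing uses σ = FWHM/√(8 ln 2) per axis in voxel units (8 mm default),
zero-padded boundaries, applied after brain masking and followed by
re-masking, so maps are exactly zero outside the brain; no edge
renormalization is applied (values within ~1 FWHM of the mask edge are
attenuated — identical for all subjects, so it cancels in the GLM).
The brain mask is GM+WM+CSF probability > 0.5, hole-filled, largest
connected component. The junction zone is read as the *intermediate* band
[μ_GM + 0.5σ_GM, μ_WM − 0.5σ_WM] — the only reading that yields the
gray–white transition zone — with class statistics over probability > 0.5
voxels of the bias-corrected T1. nFSI defaults to the z-score form
(unit-comparable effect sizes across subjects); a ratio form is switchable.
The group analysis mask is the voxelwise intersection of the subjects'
individual masks.

## Single-case statistics

OLS rows are the n controls plus the patient; columns are intercept,
patient indicator, and centered covariates (age everywhere, TIV only for
GMC/GMV). df = (n+1) − rank(X). The covariate-free case reduces exactly to
Crawford–Howell (asserted at 1e-10). Two-tailed maps are thresholded on
both signs, each side at the stated α by default (the α/2-per-side
convention is a switch). Clusters use 26-connectivity, no extent threshold
(`min_cluster = 0`), matching the any-suprathreshold-voxel definition of a
finding; no visual filtering of any kind is applied.

**FWE.** Default is Bonferroni over the mask (always valid, conservative
under smoothing). The random-field-theory alternative solves
Σ_d R_d·ρ_d(t) = α for the expected Euler characteristic of a t field
(Worsley densities, d = 0..3), with resel counts from a box equivalent of
the mask and per-axis FWHM estimated from standardized residuals via the
variance of first differences (FWHM = √(4 ln 2/λ), clipped at 1 voxel,
needs ≥ 10 residual maps). Validation: on periodic 32³ null t fields
(FWHM 6 voxels, df 47) the RFT threshold matches the 95% quantile of the
*continuum* field maximum — lattice maxima refined by local cubic-spline
interpolation — to well under 2%; against raw lattice maxima it is ~2–3%
conservative, which is the expected discretization gap, and the empirical
family-wise rate at the RFT threshold is below 0.05. Periodic simulations
are compared against the pure 3-D resel term (a torus has no boundary
resels). Real-data thresholds from SPM would differ in detail (warped-mask
resel geometry, small-volume behaviors).

## Evaluation

A control with ≥ 1 suprathreshold cluster in a leave-one-out analysis is a
false positive; specificity = true negatives / n with a Wilson 95% CI
(Clopper–Pearson switchable). A cluster is concordant if any voxel touches
the target mask (lobar/resection-level granularity; a peak-inside rule is
available). Colocalization of two maps means voxel coincidence or
26-neighborhood contact of their clusters (6-connectivity switchable).
Odds ratios use Woolf's log method with Haldane–Anscombe +0.5 on zero
cells; the worked 2×2 table (8,6;2,11) gives OR 7.33, CI 1.16–46.24.

## Problem sizes

Defaults used by the test suite and acceptance script, chosen as the
smallest sizes at which the statistical assertions have adequate power:
48³ grids at 1.5 mm; 20-control cohorts for specificity; 20 patients per
strong-lesion condition (6 per weaker sweep level); 210 null leave-one-out
analyses for Bonferroni calibration; 2,000 (tests) / 800 (acceptance
script) simulated t fields for the RFT oracle; 10 deformations for volume
conservation.

## Known limitations

- Phantom geometry is convex and three-compartment; specificity estimates
  on phantoms are optimistic relative to real cohorts (no registration
  error, no vascular/dural classes, no age-related atrophy structure).
- The EM segmentation has no spatial priors and would need them for real
  brains; multispectral gain is asserted only as "not worse" on phantoms.
- The per-axis smoothness estimator is slightly biased at small df; the
  RFT path is therefore the non-default FWE mode.
- Lesion effect sizes are synthetic; sensitivity numbers characterize the
  pipeline's behavior under the phantom's contrast, not clinical yield.
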