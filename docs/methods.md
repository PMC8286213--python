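# Methods

This note documents the models, conventions and numerical choices behind
petharm: what the simulator emulates and deliberately does not, how each
metric is defined, and where the design was genuinely open.

## Scope and conventions

petharm analyses PET acquisitions of the NEMA IEC body phantom for the
quantitative harmonisation of Ga-68 multi-centre studies: recovery
coefficients (RC), contrast recovery (CRC), background variability (BV),
image roughness (IR), peak-to-valley ratios (PTV) of edge artifacts,
mean ± 2 SD specification limits across scanners, and Bland–Altman
agreement of lesion SUVs between reconstruction variants.

All internal units are millimetres and kBq/ml.  Images are 3D arrays
indexed (x, y, z) with axial slices along the third axis, voxel-centre
origin convention, phantom frame centred on the phantom.  NIfTI-1 is the
canonical on-disk format; DICOM series are read-only.

## Phantom model

The six spheres (37, 28, 22, 17, 13, 10 mm inner diameter) sit in one
axial plane on a 114.4-mm-diameter ring at 60° spacing — the standard
layout of the physical phantom.  The torso shell is approximated by an
elliptical cylinder with 300 × 230 mm axes and 180 mm length; the exact
shoulder contour is omitted because no metric depends on it (the
background compartment volume comes out at ≈ 9.4 L, within 10% of the
nominal ≈ 9.7 L).  The lung insert is a central 50-mm-diameter cylinder
with zero activity.  Sphere walls ("cold wall" effect) and CT-based
attenuation are not modelled.

Fills are specified as concentrations at fill time with the isotope's
half-life (Ga-68: 68 min; mean positron range 2.9 mm in water, vs
0.6 mm for F-18) and an optional multiplicative residual-activity
factor (default 1.0).  Decay correction is `c · 2^(−t/T½)`.

## Simulator

The simulator generates images whose resolution, edge-artifact and noise
behaviour reproduce the *trend structure* of reconstructed scanner data.
It is entirely image-domain; there is no projection/sinogram model, no
time-of-flight, scatter, randoms or attenuation physics, and no vendor
reconstruction code.  Stages, in order:

1. **Rasterisation.**  Voxel value = background + (sphere −
   background) · f, with f the voxel fraction inside a sphere estimated
   by 3³ sub-voxel sampling (volume error < 1% even for the 10-mm
   sphere at 2.7-mm voxels).  Body and lung membership use a
   voxel-centre test.
2. **Resolution blur.**  Gaussian with FWHM = √(psf² + positron²).  The
   positron-range kernel is a Gaussian of FWHM = 2 × mean range × 0.85
   — the true annihilation-point distribution is cusp-shaped, but only
   the relative Ga-68 vs F-18 behaviour matters here; the factor is a
   module constant.
3. **Edge enhancement** (PSF and penalised-likelihood families only).
   Difference-of-Gaussians sharpening, out = (1+α)·img − α·G₅ₘₘ(img),
   clipped at zero.  This produces the Gibbs-type overshoot rim at
   concentration boundaries.  Default α = 3 with a 5-mm wide kernel:
   chosen so that a sharp reconstruction (w = 2 mm) shows a clear
   rim-and-valley on the 37-mm sphere (PTV ≈ 1.10) and the 13-mm sphere
   exhibits the characteristic RC_max overshoot above 1, while a 6.4-mm
   post filter suppresses the mean PTV to ≤ 1.05.  These are simulator
   knobs that reproduce reported trend directions, not claims about any
   vendor algorithm.
4. **Noise.**  Zero-mean Gaussian with voxelwise SD = noise_level ·
   √(local mean · reference), i.e. proportional noise with a
   Poisson-like square-root signal dependence; the white field is
   smoothed by a correlation kernel (default 4 mm FWHM) and renormalised
   to unit marginal variance so correlation length and amplitude are
   independent dials — this is what lets BV (between-ROI) and IR
   (within-ROI) decouple.  Values are clipped at zero.  The default
   noise_level of 0.25 was calibrated once against the reported noise
   ranges of harmonised reconstructions (BV ≈ 3–7%, IR ≈ 6–9%).
5. **Post filter.**  Gaussian of the user's width w.
6. **Calibration bias.**  A final multiplicative factor per scanner.

The penalised-likelihood family is emulated with
α(β) = α₀·e^(−β/400) and internal smoothing s(β) = 7·(1 − e^(−β/400)) mm,
so β = 200 shows strong overshoot and noise while β ≥ 800 suppresses
both — matching the reported direction of every β trend (PTV, RC, BV,
IR).  Noise is injected after edge enhancement and before the post
filter, mirroring where smoothing acts in real reconstruction chains.

Randomness: one master seed; the noise stage and the ensemble sampler
derive child seeds by fixed offsets, so any stage can be re-run
independently and the full chain is a pure function of (inputs, seed).

**What the generator does not emulate** — and hence what green tests do
not certify about real data: count-statistics noise (noise presets are
calibrated to reported BV/IR ranges, not NECR), reconstruction
non-linearities and convergence effects, sphere cold walls, attenuation
or scatter residuals, patient motion.  Conclusions transfer to real
acquisitions only insofar as those enter through resolution, overshoot,
correlated noise and calibration bias.

## Segmentation

Sphere VOIs are 3D isocontours at 50% of the maximum voxel within a
spherical search region around the nominal centre (radius
max(0.75 d, d/2 + 10 mm)): the mask is the 26-connected supra-threshold
component containing that maximum.  A mask exceeding 8× the nominal
volume or filling > 90% of the search region means the level set merged
with the background (low contrast) and raises a segmentation error —
at a 2:1 fill this is the normal outcome for small spheres, because the
50% level of a blurred low-contrast sphere falls below the background.
The threshold uses the plain maximum, with no background correction.

The background battery replicates six concentric circles (diameters
equal to the sphere diameters) at 12 angular positions × 5 slices = 360
ROIs, 60 per size.  The protocol fixes only those counts; the geometry
here is 12 positions at 30° spacing (offset 15° from the sphere angles)
on a 95-mm ring, slices at 0, ±10, ±20 mm.  The ring radius keeps the
largest (37-mm) circles clear of the sphere VOIs, the lung insert and
the body outline; any residual collision triggers a deterministic
±10-mm radial fallback, and an error if none is admissible.  Voxel
membership in circles uses a centre-in test, keeping counts integral.

The peak ROI is a 1-cm³ sphere (radius 6.20 mm) realised as
fractional-occupancy voxel weights (volume within 2% of 1 cm³ on all
supported grids).  Candidate centres are the voxel centres of the mask
dilated by one voxel; the ROI may extend outside the mask.  Exact ties
are broken by proximity to the hottest voxel, then lowest (z, y, x).

## Metrics

* RC = C_m / C_dc with C_m the mask maximum (RC_max), mask mean
  (RC_mean), or peak-ROI mean (RC_peak); C_dc is the fill concentration
  decay/residual-corrected to scan time.
* CRC = (C_m − C_bkg,m)/(C_dc − C_bkg,dc); C_bkg,m is the grand mean of
  the 60 largest-size battery ROIs (the most stable background
  estimate; the protocol does not specify which size feeds the CRC).
* BV_r = sample SD of the 60 ROI means / grand mean (K−1 denominator).
* IR_{r,k} = within-ROI voxel sample SD / ROI mean (I−1 denominator);
  reported per size as the mean over the 60 ROIs, with the SD retained
  in the output for diagnostics.  Whether published plots use mean or
  median across ROIs is not stated; the choice is recorded in output
  metadata.

Note that RC_mean through a 50% isocontour is *intrinsically* below 1
even for a noiseless, unblurred digital phantom: boundary voxels with
fractional occupancy ≥ ~0.43 enter the mask and dilute the mean (≈ 0.95
for the 37-mm sphere at 2-mm voxels, down to ≈ 0.8 for the 10-mm).
Chain-unbiasedness is therefore verified with ground-truth *interior*
masks (voxels fully inside the nominal sphere), exposed as
`petharm.ground_truth_masks`; with those, an identity simulation gives
RC = CRC = 1 exactly.

## Edge-artifact profiles

For each sphere the axial slice with the largest mask area is selected
(ties resolved toward the mask centroid).  Six profiles through the
footprint centroid at 30° spacing are sampled by bilinear interpolation
at 0.5-mm steps, extending one footprint diameter beyond the region on
each side.  A footprint narrower than two voxels raises a
profiles-unavailable error (the small-sphere situation on coarse grids).

PTV = (maximum over the whole profile) / (minimum over the central 40%
of the in-region span).  The valley is restricted to the central
portion because the artifact's valley forms at the region centre,
whereas the footprint edge always dips toward half-maximum regardless
of any artifact; an artifact-free flat-top therefore scores PTV = 1 and
an overshoot rim scores PTV > 1.  Footprints too small to hold three
central samples fall back to the whole in-region span.

Surfaces are classified per sphere: **flat** if the median in-region
max/valley ratio is below 1.02; **concave** (rim and valley — PTV
meaningful) if the majority of profiles peak within 20% of the
footprint edge; **conical** (partial-volume dome — PTV not measurable)
if the majority peak in the central 30%; otherwise undefined.  The
thresholds are module constants; the underlying distinction is made by
eye in practice.  Mean PTV (± sample SD over the six profiles) is
reported only for concave/flat shapes.

## Harmonisation

Across-scanner aggregation uses the sample SD (n−1): with ~6 sites the
sample/population distinction is material, and the choice is recorded
in output metadata.  Specification limits are mean ± k·SD (default
k = 2) per sphere and metric; zero dispersion yields a degenerate-limits
warning.  Compliance is a closed-interval test, reporting the percent
deviation from the violated bound.  Welch's t test
(unequal-variance, Welch–Satterthwaite df) compares metric groups, raw
p values with no multiplicity correction.

The shipped `limits_ga68_table2.csv` carries the published Ga-68
bounds for conventional (OSEM/OSEM+TOF) and advanced (PSF /
penalised-likelihood) reconstructions.  The F-18 accreditation bands
are not shipped; user tables in the same CSV schema can be loaded.

## Clinical agreement

The clinical stage consumes per-lesion SUV tables (it does not compute
SUVs from images — its inputs are delineated-lesion values).  SUVs are
natural-log transformed, so limits of agreement back-transform to SUV
ratios; Bland–Altman limits are mean ± 1.96 SD of the paired log
differences, with a strict-inequality outside count, plus a paired t
test (df = n − 1).

The synthetic cohort generator draws 24 lesions (13 prostate, 9 lymph
node, 2 bone — the published cohort composition; the source itself
reports both 22 and 24 lesions, and 24 is used) lognormally around
site-specific SUV_max baselines (9 / 7 / 5 g/ml, between-lesion log-SD
0.5 — typical PSMA-avid lesion spreads).  Each penalised reconstruction
applies a multiplicative bias exp(0.12 · (900 − β)/900) — monotone
decreasing, ≈ +9% at β = 200, crossing 1.0 in the 800–1000 range — plus
lognormal measurement noise (log-SD 0.05).  Under these defaults the
paired t test vs the reference is significant for β ≤ 600 and β = 1200
but not for 800/1000, reproducing the reported clinical pattern.

## Numerical choices and degenerate inputs

* Gaussian filtering uses zero-padding; the phantom sits well inside
  the grid, so total activity is conserved to < 0.1%.
* A uniform (zero-contrast) image has no 50% level set and raises a
  segmentation error rather than returning a bogus mask.
* Peak ROI means are computed by occupancy-weighted correlation, so the
  reported "1-cm³" volume is grid-independent to < 2%.
* Monotonicity of PTV vs smoothing holds to within ~0.01 interpolation
  jitter once the artifact is suppressed (the residual ratio reflects
  dome curvature, not the artifact).
* All CSV/JSON outputs are written with fixed float formatting and
  sorted keys; rerunning an experiment with the same config and seed
  reproduces them byte-for-byte.

## Problem sizes

Default analyses run at clinical voxel sizes (2.7 × 2.7 × 3.3 mm);
validation chains use 2-mm isotropic grids, and the flat-top PTV
reference case uses 1-mm voxels.  Ensemble studies use 20 replicates of
6 scanners; clinical power checks use 50 seeded cohorts.  These sizes
were chosen so each study completes in minutes on a single core while
keeping sampling error well inside the asserted tolerances.
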