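# Methods

`spectseg` benchmarks two segmentation algorithms — Otsu's global threshold
and the Chan–Vese active-contour model solved by iterative
convolution-thresholding (ICTM) — on simulated thyroid SPECT images, the
setting in which the *active* (tracer-avid) gland volume has to be measured
for radioiodine therapy planning. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Digital phantom

The gland is a parametric butterfly: two ellipsoidal lobes (semi-axes
20 × 9 × 10 mm at unit scale, in z/y/x) joined by an ellipsoidal isthmus,
wrapped around a 16 mm-diameter air-filled tracheal tube and immersed in a
cylindrical water bath (radius 55 mm, height 120 mm) surrounded by air.
Arrays are indexed (z, y, x) with y the anterior–posterior axis; voxels are
isotropic, 4.42 mm by default, on a 128³ grid.

A single scale factor multiplies the lobe and isthmus semi-axes and is
solved by bisection against the voxel count of the target volume
(20/35/50 ml); because symmetric boundary voxels can enter the discrete
shape in groups, a final adjustment adds or removes the voxels nearest the
analytic surface so the count matches `round(V / voxel volume)` exactly
(the gland centre is also jittered off the lattice by a fixed sub-voxel
offset to break ties). The voxelized volume is therefore within half a
voxel volume (0.043 ml) of the request. The hotspot is the set of voxels
nearest the right-lobe centre whose count is `round(fraction × N_thyroid)`
(default fraction 0.10) — an approximately spherical region that leaves the
total gland volume unchanged. Hotspot size and position are free
parameters; nothing in the benchmark pins them, so the defaults are fixed
once and used everywhere.

## Image formation

Two engines share the same stated imaging parameters: 60 projections over
360°, 128×128 bins of 4.42 mm, a depth-independent Gaussian system PSF, and
Poisson counting noise.

**System resolution.** The parallel-hole formula
`R_sys = sqrt(R_int² + R_coll²)`, `R_coll = d·(L_eff + b + g)/L_eff` with
`L_eff = L − 2/μ_Pb` uses μ_Pb = 2.37 mm⁻¹ (lead at 140 keV) and a
collimator-to-crystal gap g = 2.5 mm; with the default LEHR geometry
(d = 1.5 mm, L = 35 mm, R_int = 4.5 mm, b = 100 mm) it evaluates to
7.50 mm, which is the PSF FWHM used throughout.

**Full engine.** The projector rotates the volume about z by bilinear
resampling implemented as an explicit gather with precomputed weights,
applies per-voxel attenuation factors `exp(−∫μ dl)` toward the detector
(μ_water = 0.0155 mm⁻¹ for water/thyroid, 0 for air and trachea — the
thyroid is water-equivalent), sums along the ray axis and convolves with
the PSF (zero-padded symmetric kernel). Backprojection applies the same
weights as a scatter, so forward/back are exact numerical adjoints (machine
precision on random volumes) — the property OSEM's multiplicative update
needs. Counts are scaled so the across-angle mean of total expected counts
is 100,000 before Poisson sampling. OSEM uses angle-interleaved subsets
(default 6 × 12 iterations), a uniform unit start inside the cylindrical
field of view, a 10⁻¹² guard on ratio denominators, and no post-filter.
After 72 sub-updates OSEM partially deconvolves the modelled PSF: a
reconstructed point source measures ≈ 4.5 mm FWHM rather than 7.5 mm.

**Fast surrogate.** For the 48-case grid the chain is collapsed into the
image domain: blur the activity map with the 3D system PSF, multiply by a
count scale, Poisson-sample per voxel, rescale. The scale is calibrated by
bisection so that the coefficient of variation (std/mean) measured in a
background region away from the gland equals 0.8 for the 20 %-background
case (tolerance ±0.05, averaged over three realisations); the constant is
then held fixed for every case. The surrogate's noise is spatially white,
whereas reconstructed-image noise is correlated at roughly the PSF scale;
the marginal noise level — which is what the calibration pins down and
what global thresholding responds to — is matched.

A consequence worth stating plainly: at a background CoV of 0.8, several
percent of background voxels exceed any threshold placed ~2σ above the
background mean, so a global threshold of a volume with tens of thousands
of background voxels inevitably collects a large absolute number of false
positives. The benchmark statistics under the default calibration reflect
this (pooled volume errors of hundreds of percent at the higher background
levels, not the ~10 % seen at low backgrounds); the comparative conclusions
(Chan–Vese deviates less and scores significantly higher DSC) are
unaffected. Passing tests therefore demonstrate correct mechanics and the
methods' *relative* behaviour, not clinical-level absolute accuracy of real
reconstructed images at this noise setting.

## Pre-processing

In order: (1) subtract the background-ROI mean, clamping negatives to zero
(ROIs an operator would draw by hand are replaced by either label-derived
"validation-mode" ROIs — a 1-voxel erosion of the true gland, and water at
least 3 voxels away from it — or an automatic rule: largest connected
component of the top 10 % of the robust intensity range — a
99.5th-percentile maximum — with percentiles computed over the
reconstructed support, voxels above 5 % of that maximum, so the faint blur
fringe around the object does not dominate); (2) cap values
at the thyroid-ROI mean computed after step 1, which keeps a hotspot from
splitting the gland into two classes; (3) quantize [0, cap] to 0–255 with
half-up rounding, the cap mapping to 255 exactly. Capping in float before
quantization is a choice; the alternative order differs by at most one grey
level. The benchmark uses validation-mode ROIs so that the method
comparison is not confounded by ROI placement. Wavelet denoising is
deliberately omitted.

## Segmentation

**Otsu.** All 255 candidate thresholds are scanned with cumulative-moment
arithmetic; the minimiser of ω_b σ_b² + ω_f σ_f² is returned, ties broken
to the smallest threshold and zero-weight classes contributing zero. The
foreground is the bright class (values ≥ t). A brute-force oracle (direct
per-threshold class statistics) confirms the scan on random histograms.

**Chan–Vese / ICTM.** The piecewise-constant energy is minimised over a
binary indicator u by alternating: recompute the region means c1/c2 from u;
set u ← 1 exactly where
`λ1(f−c1)² − λ2(f−c2)² + sqrt(π/τ)·G∗(1−2u) < 0`.
The Gaussian interface kernel has variance 2τ in voxel units (σ = √0.6
voxels at the default τ = 0.3), truncated at 4σ with replicate padding; the
volume-penalty term ν is 0 and the area weight is absorbed into the
sqrt(π/τ) factor. λ1 = k·sqrt(π/τ) and λ2 = λ1 (symmetric fidelity,
configurable); k comes from a per-(volume, background) lookup table, or
from `select_k`, which scans a geometric k grid and returns the centre of
the widest plateau of the volume-vs-k curve (consecutive candidates whose
volumes agree pairwise within 5 %), falling back to the table when no
plateau of length ≥ 2 exists — the plateau rule is this package's
documented choice of selection criterion. Initialisation is the Otsu mask
(deterministic, content-aware; a centred sphere is available); iteration
stops on exact mask equality or at 500 sweeps (flagged, not raised); a mask
that empties or fills the volume raises a collapse error carrying k. Both
the mean update and the thresholding step decrease the relaxed energy, so
the recorded energy trace is non-increasing (asserted to 10⁻⁸ relative).

Because intensities are 0–255, k values of order 10⁻⁴–10⁻² put the fidelity
term (λ1·(Δf)² ~ 10⁻³·10⁴) on the same scale as the interface term
(sqrt(π/0.3) ≈ 3.2), which is why small k smooths aggressively and large k
approaches pure thresholding.

## Evaluation

DSC = 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks and 0 when exactly
one is empty. Volume agreement is summarised on relative volumes
r = V̂/V: MAE = mean|r−1|·100 (percent), MRV = mean r, and S the sample
standard deviation of r (ddof 1) — per volume group and pooled ("20-50").
The method comparison is a classical two-sided paired t-test on the 48
per-case DSC differences (all-zero differences → t=0, p=1; zero variance
with non-zero mean → p=0 with a warning). Misclassification maps sum missed
and false-positive voxels along the anterior–posterior axis.

## Benchmark orchestration

Per-case seeds are derived as CRC32 of
`master_seed|volume|background|hotspot` (reproducible, independent noise
across cases, < 2³¹). Phantoms are cached per volume; every configured cell
is enumerated and a failing case is warned about and excluded rather than
silently skipped. The background sweep (0–70 % in 5 % steps, homogeneous
50 ml gland) averages DSC over 5 realisations per level because a single
realisation gives a visibly jagged curve.

Problem sizes used by the shipped tests and the acceptance script: the full
128³ grid for the 48-case benchmark, noise calibration and parameter
recovery; 64³ for unit-level pipeline tests; 16³–32³ for projector/OSEM
property checks. The full grid with the fast engine runs in about a minute
on one CPU; the OSEM engine is available through the same configuration for
full-fidelity single cases.

## Known limitations

- The phantom is a smooth parametric solid: no shape irregularity, lesion
  texture, or anatomical variability; one hotspot at a fixed site.
- The surrogate's white noise and the deterministic projector omit scatter,
  depth-dependent resolution, septal penetration tails and
  reconstruction-correlated noise.
- OSEM resolution recovery means the effective PSF of full-engine images is
  narrower than the nominal 7.5 mm.
- Automatic ROI derivation assumes a single bright gland on a darker
  background; it is not robust at the benchmark's highest noise levels, and
  the benchmark uses label-derived ROIs instead.
- Threshold-type segmentation of a PSF-blurred object is not volume-neutral:
  even noise-free, the recovered volume carries a systematic offset of a few
  percent set by where the threshold falls on the partial-volume edge
  profile.
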