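# spectseg

Simulated thyroid SPECT images and a head-to-head benchmark of two
segmentation algorithms for measuring the **active thyroid volume** — the
quantity that radioiodine therapy planning for hyperthyroidism needs from
⁹⁹ᵐTc-pertechnetate SPECT. The package is for medical-physics and imaging
researchers who want a fully reproducible, parameter-matched sandbox in
which threshold-based and active-contour segmentation can be compared
without access to a gamma camera.

## What it does

- **Phantoms** — butterfly-shaped digital thyroid glands (two ellipsoidal
  lobes + isthmus around an air-filled trachea in a water bath) of 20, 35
  and 50 ml on a 4.42 mm voxel grid, with configurable relative background
  activity (5–20 %) and a hotspot at 100–250 % of the gland's activity
  concentration.
- **Image formation** — a deterministic parallel-beam projector with
  uniform water attenuation and a 7.5 mm FWHM Gaussian system PSF
  (computed from the LEHR collimator geometry), 60 projections scaled to
  100,000 counts each, Poisson noise, and OSEM reconstruction
  (6 subsets × 12 iterations, no post-filter); plus a fast image-domain
  surrogate whose noise is calibrated to a background coefficient of
  variation of 0.8 at the 20 % background level.
- **Segmentation** — both algorithms implemented from scratch:

  *Otsu*: exhaustive minimisation of the weighted within-class variance
  σ_w²(t) = ω_b(t)σ_b²(t) + ω_f(t)σ_f²(t) over the 256-level histogram.

  *Chan–Vese via ICTM*: the piecewise-constant Mumford–Shah energy
  F(c₁,c₂,C) = μ·area(C) + λ₁∫_in |u₀−c₁|² + λ₂∫_out |u₀−c₂|²
  minimised by iterative convolution-thresholding, with
  λ₁(k,τ) = k·√(π/τ), τ = 0.3, and a per-case fidelity scale k.
- **Evaluation** — Dice similarity coefficient, MAE/MRV/SD of relative
  volumes per gland size, per-case Otsu threshold tables, misclassification
  projections, a paired t-test on DSC between methods, and a DSC-vs-
  background sweep (0–70 %).

## Worked example

```bash
python examples/segment_single_case.py
```

prints (35 ml gland, 10 % background, 200 % hotspot, fast engine):

```
calibrated noise scale: 7.67 counts per unit activity
true volume: 34.97 ml
Otsu      : t= 40  volume= 86.35 ml  DSC=0.537
Chan-Vese : k=0.03  volume= 86.35 ml  DSC=0.537  (1 iterations, converged=True)
```

At the benchmark's calibrated noise level (background CoV 0.8) a global
threshold admits a few percent of the many background voxels, so both
methods overestimate this mid-background case (with k = 0.03 the Chan–Vese
fidelity term dominates and its mask coincides with Otsu's here). At low
background the same pipeline behaves like clinical low-noise data: the
20 ml gland at 5 % background with a 250 % hotspot gives
`Otsu: t=74, 20.8 ml, DSC 0.82`. Other scripts in `examples/` build
and save phantoms, run the full projector + OSEM path, reproduce the
48-case benchmark tables, and sweep the background level.

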