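"""Full image-formation path on a coarse grid: project, add noise, reconstruct.

Forward-projects a 20 ml phantom over 60 angles with water attenuation and
the 7.5 mm system PSF, scales to 100,000 counts per projection, adds Poisson
noise, and reconstructs with OSEM (6 subsets x 12 iterations, no post-filter).
A 64^3 grid keeps the run to about a minute.
"""

import numpy as np

import spectseg as ss
from spectseg.simulate import Projector, attenuation_map, default_angles

print(f"system resolution: {ss.system_resolution_fwhm(ss.CollimatorSpec()):.2f} mm")

phantom = ss.place_hotspot(ss.build_phantom(20, 4.42, (64, 64, 64)))
activity = ss.compose_activity(phantom, ss.CaseSpec(20, 0.10, 1.5, seed=3))

angles = default_angles(60)
noiseless = ss.forward_project(activity, phantom, angles)
noisy = ss.scale_and_add_noise(noiseless, mean_counts_per_projection=1e5, seed=3)
print(f"mean counts per projection: {noisy.totals().mean():.0f} (target 100000)")

projector = Projector(
    activity.values.shape, 4.42, angles, psf_fwhm_mm=7.5, mu=attenuation_map(phantom)
)
recon = ss.osem_reconstruct(noisy, projector, subsets=6, iterations=12)
gland_mean = recon.values[phantom.gland_mask].mean()
bg_mean = recon.values[phantom.labels == ss.Label.WATER].mean()
print(f"reconstructed gland/background intensity ratio: {gland_mean / bg_mean:.2f}")
recon.to_nifti("recon20.nii.gz")
print("wrote recon20.nii.gz")
# The ratio is well above 1: reconstruction recovers the gland contrast the
# activity map prescribed (10x here), degraded by the PSF and counting noise.
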