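"""Segment one simulated case with both methods and score them.

Simulates the 35 ml gland at 10 % background with a 200 % hotspot using the
fast surrogate (noise calibrated to the benchmark's background CoV), applies
the pre-processing chain, then runs Otsu and the ICTM Chan-Vese model and
reports volumes and Dice scores against the ground-truth gland.
"""

import spectseg as ss

phantom = ss.place_hotspot(ss.build_phantom(35))
noise_scale = ss.calibrate_noise(phantom, target_cov=0.8, bg_level=0.20, seed=0)
print(f"calibrated noise scale: {noise_scale:.2f} counts per unit activity")

case = ss.CaseSpec(35, 0.10, 2.0, seed=42)
activity = ss.compose_activity(phantom, case)
recon = ss.degrade_fast(activity, noise_scale=noise_scale, seed=case.seed)

rois = ss.derive_rois(recon, truth=phantom)
q = ss.preprocess_volume(recon, rois)

otsu_mask = ss.otsu_segment(q)
t = ss.otsu_threshold(ss.histogram_256(q)).threshold
k = ss.K_TABLE[(35, 0.10)]
state = ss.ictm_segment(q, ss.ICTMConfig(tau=0.3, k=k))

truth = phantom.gland_mask
print(f"true volume: {phantom.true_volume_ml:.2f} ml")
print(
    f"Otsu      : t={t:3d}  volume={otsu_mask.segmented_volume_ml:6.2f} ml  "
    f"DSC={ss.dsc(otsu_mask, truth):.3f}"
)
print(
    f"Chan-Vese : k={k:g}  volume={state.mask.segmented_volume_ml:6.2f} ml  "
    f"DSC={ss.dsc(state.mask, truth):.3f}  "
    f"({state.iterations} iterations, converged={state.converged})"
)
# DSC near 1 means the mask overlaps the true gland almost voxel-for-voxel;
# the volume row shows each method's over- or under-estimate directly.
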