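"""Run the 48-case benchmark grid and print the summary tables.

Crosses 3 gland volumes x 4 background levels x 4 hotspot contrasts, each
segmented by both methods, then prints the per-volume MAE/MRV/SD tables, the
per-case Otsu thresholds, and the paired t-test on DSC. Takes a couple of
minutes with the fast engine. Pass --quick for a reduced 8-case grid.
"""

import argparse

import spectseg as ss

ap = argparse.ArgumentParser()
ap.add_argument("--quick", action="store_true", help="2 volumes x 2 backgrounds x 2 hotspots")
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

cfg = ss.BenchmarkConfig(master_seed=args.seed)
if args.quick:
    cfg = ss.BenchmarkConfig(
        volumes=(20, 50), backgrounds=(0.05, 0.20), hotspots=(1.0, 2.0),
        master_seed=args.seed,
    )

result = ss.run_grid(cfg, outdir="benchmark_results")
print(f"noise scale: {result.noise_scale:.2f};  failed cases: {len(result.failures)}")

for method in ("chan_vese", "otsu"):
    print(f"\n=== {method}: MAE (%), mean relative volume, SD per volume group ===")
    print(result.summary(method).to_string(index=False))

print("\n=== Otsu thresholds per case ===")
print(result.otsu_threshold_table().to_string())

t, p = result.dsc_test()
print(
    f"\npaired t-test on DSC (Chan-Vese vs Otsu): t={t:.3f}, p={p:.4f}; "
    f"mean DSC {result.mean_dsc('chan_vese'):.3f} vs {result.mean_dsc('otsu'):.3f}"
)
# A positive t with small p says the Chan-Vese masks overlap the truth
# significantly better than the Otsu masks, case by case.
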