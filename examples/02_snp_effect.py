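"""Quantify how within-probe SNPs depress hybridization log2 ratios.

Long-oligo CGH probes that contain SNPs between test and reference genomes
bind the test DNA less well, so their log2 ratio drops by about -0.5 per
SNP — mimicking a deletion. This script recovers that effect from
simulated data by OLS regression of ratio on SNP count, shows the group
medians, and profiles the effect by SNP position within the probe.
"""

from acghcnv import (
    Genome, SimParams, fit_snp_regression, make_probe_grid, make_snp_map,
    position_profile, simulate_profiles, standardize,
)

genome = Genome([("chr1", 40_000_000)])
params = SimParams(noise_sd=0.4, repeat_fraction=0.0, seed=10)

probes = make_snp_map(make_probe_grid(genome, params), ["test"],
                      snp_rate=0.006, seed=11)
normal, _ = simulate_profiles(probes, [], params, seed=12)["test"]

fit = fit_snp_regression(normal, probes, "test")
print(f"probes: {fit.n}")
print(f"OLS slope (log2 ratio per SNP): {fit.slope:.3f} +- {fit.stderr:.3f}, "
      f"R^2 = {fit.r_squared:.3f}, P = {fit.p_value:.2e}")
print("group medians (0 / 1 / 2 / 3+ SNPs):",
      " ".join(f"{fit.group_medians[g]:.2f}" for g in ("0", "1", "2", "3+")))
print("-> each additional SNP costs ~0.4-0.5 log2 units; two SNPs roughly "
      "halve the apparent signal.")

medians = position_profile(normal, probes, "test")
print("\nmedian ratio of single-SNP probes by folded position category "
      "(1 = probe edge, 6 = center):")
print(medians.round(3).to_string())
print("-> central SNPs disturb hybridization more than edge SNPs "
      "(the simulated weight ramp).")

std = standardize(normal, probes, "test")
fit_std = fit_snp_regression(std, probes, "test")
print(f"\nafter per-group standardization the residual slope is "
      f"{fit_std.slope:.4f} (SNP effect removed).")
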