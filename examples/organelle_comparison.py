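"""Patient-vs-control organelle statistics with the normality-gated test:
per-cell peroxisome counts (roughly Poisson, so close to normal at these
means) go to a t-test, while the skewed per-organelle size distribution is
routed to a Mann-Whitney U."""

from ldscreen import compare_groups, simulate_organelle_groups

g = simulate_organelle_groups(n_cells=150, count_ratio=1.3, size_ratio=0.8,
                              seed=5)

counts = compare_groups(g["counts_patient"], g["counts_control"])
print(f"counts/cell: patient {counts.mean_a:.1f} vs control "
      f"{counts.mean_b:.1f} -> {counts.test_used}-test, p = {counts.p_value:.2e}")

sizes = compare_groups(g["sizes_patient"], g["sizes_control"])
print(f"organelle size: patient median {sizes.median_a:.3f} vs control "
      f"{sizes.median_b:.3f} um^2 -> {sizes.test_used}, p = {sizes.p_value:.2e}")

print("\nMore-but-smaller peroxisomes in the disease group: both contrasts")
print("are detected, each by the test its distribution calls for.")
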