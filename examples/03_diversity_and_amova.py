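"""Windowed diversity, per-strain inbreeding, and hierarchical AMOVA.

Computes pi and Tajima's D in 5-kb windows, heterozygosity-based inbreeding
coefficients per strain (hybrids come out negative), and the three-level
AMOVA partition of genetic variance.
"""

from mycopop.diversity import amova, strain_het, window_tajima_d
from mycopop.simulate import SimulationConfig, simulate_genotypes
from mycopop.variant_io import thin_by_distance

config = SimulationConfig(n_loci=4000, seed=3)
matrix, truth = simulate_genotypes(config)
assignment = truth.assignment()

win = window_tajima_d(matrix, window_size=5000)
covered = win[win["n_sites"] > 0]
print(f"windows with sites: {len(covered)}")
print(f"mean per-bp pi: {covered['pi'].mean():.2e}")
print(f"mean Tajima's D: {covered['tajima_d'].dropna().mean():.3f}")

# inbreeding per group: cultivar-like groups simulate high F, hybrids negative
for g in assignment.groups(include_outliers=True):
    sub = matrix.take_strains(assignment.members(g))
    f_mean = strain_het(sub)["F"].mean()
    print(f"mean inbreeding F in group {g}: {f_mean:+.3f}")

table = amova(thin_by_distance(matrix, 1000), assignment)
print("\nAMOVA (outlier strains excluded):")
print(table.table.round(2).to_string(index=False))
# Percent columns show how much variance lies among populations, among
# strains within populations, and within (heterozygous) strains.
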