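"""Generate a small synthetic cohort and build subject connectomes.

The generator produces, for every subject, per-region cortical-thickness
vertex samples and regional BOLD-like time series, plus a demographics
table with site, group, age, sex, head motion and clinical scores.

Morphological connectivity between two regions is one minus the
Jensen-Shannon divergence (in bits) of their kernel-smoothed thickness
densities; functional connectivity is the Pearson correlation of their
time series.
"""

import numpy as np

import cereconn as cc
from cereconn import synth

# A small cohort: the defaults reproduce the full study size
# (228 HC / 208 MS / 200 NMOSD over 7 sites) but take longer.
cfg = synth.SynthConfig(
    n_per_group={"HC": 10, "MS": 10, "NMOSD": 10},
    n_sites=3,
    cerebral_regions=[],  # cerebellum only, for speed
    n_vertices_per_region=80,
    n_timepoints=150,
    n_genes=300,
    seed=7,
)
data = synth.generate_all(cfg)

print("cohort head:")
print(data.cohort[["id", "site", "group", "age", "sex", "fd"]].head())
print()
print("group counts:", data.cohort.group.value_counts().to_dict())

# Demographic comparability: chi-squared test of sex by group
table = data.cohort.groupby(["group", "sex"]).size().unstack().to_numpy()
chi2, p = cc.chi_square_test(table)
print(f"sex x group: chi2 = {chi2:.2f}, p = {p:.3f}")

# Build one subject's cerebellar networks
sid = data.cohort["id"].iloc[0]
cb = cfg.cerebellar_regions
morph = cc.morph_network(data.thickness[sid], cb)
func = cc.func_network(data.timeseries[sid], cfg.regions, cb, cb)

print()
print(f"subject {sid}:")
print(f"  morphological network {morph.matrix.shape}, "
      f"mean off-diagonal similarity "
      f"{morph.matrix[~np.eye(24, dtype=bool)].mean():.3f}")
print(f"  functional network {func.matrix.shape}, "
      f"mean off-diagonal correlation "
      f"{func.matrix[~np.eye(24, dtype=bool)].mean():.3f}")

# The JSD primitive itself is exposed directly
print()
print("jsd([.5,.5],[1,0]) =", round(cc.jsd([0.5, 0.5], [1.0, 0.0]), 6), "bits")
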