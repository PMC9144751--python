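"""Metabolite statistics: ANOVA + Tukey, PCA by SVD, Pearson correlations.

Simulates the n = 4 replicate sample x metabolite table (free amino
acids, total and free polyamines) and runs the analysis surface.
"""
import numpy as np

from phenoprime import (
    GrowthScenario, heatmap_matrix, metabolite_anova, pca_metabolites,
    pearson_matrix, simulate_metabolites,
)
from phenoprime.simulate import default_metabolite_effects, default_metabolite_panel

scenario = GrowthScenario()
groups = [(t, c, cond) for cond in scenario.conditions
          for t, c in scenario.treatments]
names, classes, baselines = default_metabolite_panel()
table = simulate_metabolites(
    groups, n_per_group=4, metabolites=names, classes=classes,
    effects=default_metabolite_effects(groups, names),
    baselines=baselines, noise_sd=0.2, seed=1,
)
print(f"metabolite table: {table.n_samples} samples x "
      f"{table.values.shape[1]} metabolites")

res = metabolite_anova(table)  # one-way ANOVA on ln values + Tukey vs control
n_sig = int(res.anova["significant"].sum())
print(f"ANOVA: {n_sig}/{len(res.anova)} (condition, metabolite) pairs "
      f"significant at p < 0.05")
hits = res.posthoc[res.posthoc["significant"]]
print(f"Tukey vs control: {len(hits)} significant treatment effects, e.g.")
print(hits.head(3).to_string(index=False))

pca = pca_metabolites(table)  # ln group means, unit-variance, SVD
ve = 100 * pca.variance_explained
print(f"\nPCA: PC1 {ve[0]:.1f}%, PC2 {ve[1]:.1f}% of variance "
      f"({ve[0] + ve[1]:.1f}% together)")

corr = pearson_matrix(table.log_values())
strongest = corr.r.where(~np.eye(len(corr.r), dtype=bool)).abs().max().max()
print(f"Pearson matrix: strongest off-diagonal |r| = {strongest:.2f}")

hm = heatmap_matrix(table, res)
print(f"heatmap matrix: {hm.values.shape[0]} metabolites x "
      f"{hm.values.shape[1]} treatment-condition groups, "
      f"{int(hm.significant.to_numpy().sum())} significance dots")
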