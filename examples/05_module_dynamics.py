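"""Module expression dynamics: donor medians, z-scores, fold changes.

Summarizes a synthetic time course the way the heatmap figures do:
median across donors per (condition, timepoint), per-gene z-scores, mean
per module, and log2 fold change against each condition's baseline.
"""

from pgcna import (
    SimConfig,
    fold_change_vs_baseline,
    group_medians,
    hierarchical_order,
    merge_probes_to_genes,
    module_mean_profile,
    simulate_timecourse,
    zscore_rows,
)
from pgcna.clustering import Partition

dataset = simulate_timecourse(SimConfig(seed=4))
genes = merge_probes_to_genes(
    dataset.expression, set(dataset.expression.probe_ids), dataset.annotation
)
medians = group_medians(genes)
profile = zscore_rows(medians)

truth = Partition(
    assignment={g: m for g, m in dataset.true_partition.items() if m != "M0"},
    modularity=0.0,
)
module_z = module_mean_profile(profile, truth)
print("module z-score profiles (condition C1):")
print(module_z["C1"].round(2).to_string())

fc = fold_change_vs_baseline(medians, "t0")
print("\nmodule M1 log2 fold change vs t0 (C1):")
print(module_mean_profile(fc, truth).loc["M1", "C1"].round(2).to_string())

order = hierarchical_order(module_z)
print("\nhierarchical leaf order of modules:", [module_z.index[i] for i in order])
# rows with similar dynamics cluster together; fold changes at baseline are 0
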