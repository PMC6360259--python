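"""Differential-expression overlap statistics across conditions.

Reproduces the convergence analysis pattern: DE gene sets per condition
and timepoint are compared pairwise (hypergeometric, -log10 p) and as
three-way Venn region counts.
"""

from pgcna import DESet, de_overlap_heatmap, venn_partition

population = {f"G{i:04d}" for i in range(1000)}
genes = sorted(population)

# three conditions converging on a shared induced set over time
shared = set(genes[:60])
sets = [
    DESet("C1", "24h", "induced", frozenset(shared | set(genes[100:120]))),
    DESet("C2", "24h", "induced", frozenset(shared | set(genes[130:145]))),
    DESet("C3", "24h", "induced", frozenset(shared | set(genes[150:180]))),
]

heat = de_overlap_heatmap(sets, population)
print("-log10 p overlap matrix:")
print(heat.neg_log10_p.round(1).to_string())

regions = venn_partition(*(set(s.genes) for s in sets))
print("\nVenn regions (A=C1, B=C2, C=C3):")
for region, count in regions.items():
    print(f"  {region:>3}: {count}")
# the large ABC region is the convergent common response; the singleton
# regions are condition-specific genes
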