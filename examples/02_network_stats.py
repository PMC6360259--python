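"""Build a sparsified co-expression network and inspect its counters.

The parsimonious step: of all n(n-1)/2 Spearman correlations, each gene
keeps only its 3 most positively correlated partners; the union of those
nominations (symmetrization) is the network.
"""

import numpy as np
import pandas as pd

from pgcna import retain_topk_edges, spearman_all_pairs, pair_count

rng = np.random.default_rng(0)
n_genes, n_samples = 200, 24
# two planted blocks of co-expressed genes on top of noise
signal = np.repeat(rng.normal(0, 1, (2, n_samples)), n_genes // 2, axis=0)
values = pd.DataFrame(
    8.0 + signal + rng.normal(0, 0.7, (n_genes, n_samples)),
    index=[f"G{i:03d}" for i in range(n_genes)],
)

rho = spearman_all_pairs(values)
graph = retain_topk_edges(rho, k=3)

print(f"genes: {graph.n_genes}")
print(f"pairs evaluated: {graph.n_pairs_total} (= n(n-1)/2 = {pair_count(n_genes)})")
print(f"edges retained: {graph.n_edges_retained}")
low, high = graph.edge_bounds()
# retention keeps between ceil(3n/2) and 3n edges: a ~100-1000x reduction
print(f"retention bound for k=3: [{low}, {high}]")
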