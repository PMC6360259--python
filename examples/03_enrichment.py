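"""Hypergeometric signature enrichment of network modules.

The draw is the module's genes, the successes are the signature's genes,
and the population is all genes on the platform; p values are BH-adjusted
across every (module, signature) pair tested.
"""

from pgcna import enrich_modules
from pgcna.io import SignatureDatabase

population = {f"G{i:03d}" for i in range(200)}
genes = sorted(population)
partition = {g: ("M1" if g in genes[:30] else "M2") for g in population}
signatures = SignatureDatabase(
    sets={
        "secretory_pathway": frozenset(genes[:25]),     # overlaps M1 heavily
        "cell_cycle": frozenset(genes[150:190]),        # inside M2
        "random_set": frozenset(genes[90:110]),
    }
)

table = enrich_modules(partition, signatures, population, fdr_threshold=0.1, top=30)
print(table.table[["module", "signature", "overlap", "module_size",
                   "signature_size", "p_value", "fdr"]].to_string(index=False))
# the 25/25 overlap of secretory_pathway with the 30-gene M1 is essentially
# impossible under random draws from 200 genes, hence the vanishing p
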