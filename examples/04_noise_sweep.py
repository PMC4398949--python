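"""Gene-tree error degrades congruence: a small simulation sweep.

A 12-taxon Yule species tree is observed through 200 incomplete gene trees
(half the taxa missing per gene).  With no topological noise every testable
clade is recovered at exactly 100% congruence (the perfect-signal law);
increasing the expected number of random NNI rearrangements per gene tree
drives mean congruence down.
"""

import numpy as np

from phyloconcord import (
    SimulationConfig,
    TaxonUniverse,
    concordance_table,
    simulate_gene_tree_set,
    simulate_yule_tree,
)

species = simulate_yule_tree(12, seed=42)
universe = TaxonUniverse.from_tree(species)

print("nni_rate  mean_congruence_pct  mean_n_decisive")
for rate in (0.0, 0.5, 1.0, 2.0, 4.0):
    cfg = SimulationConfig(
        n_taxa=12, n_genes=200, missingness=0.5, nni_rate=rate, seed=0
    )
    genes = simulate_gene_tree_set(species, cfg)
    rows = concordance_table(species, genes, universe)
    pcts = [r.congruence_pct for r in rows if r.n_decisive > 0]
    ndec = [r.n_decisive for r in rows]
    print(f"{rate:8.1f}  {np.mean(pcts):19.2f}  {np.mean(ndec):15.1f}")
print()
print("Rows share the same per-gene taxon sampling (coupled RNG streams),")
print("so the decline is attributable to topological noise alone.")
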