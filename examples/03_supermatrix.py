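"""Masking, filtering and concatenation with occupancy accounting.

Two small orthogroup alignments are column-masked at confidence 0.5
(columns scoring exactly 0.5 are kept), filtered on the strict >4-taxa /
>length criteria (relaxed here for the toy scale), and concatenated over a
5-taxon universe; missing taxa are gap-filled and counted as unoccupied.
"""

import numpy as np

from phyloconcord import (
    OrthogroupAlignment,
    TaxonUniverse,
    concatenate,
    filter_orthogroups,
    mask_columns,
    occupancy,
)

g1 = OrthogroupAlignment(
    "og1",
    {"sp1": "MKLVAR", "sp2": "MKLV-R", "sp3": "MKLVAR"},
    column_scores=np.array([0.9, 0.4, 0.5, 0.2, 0.8, 0.9]),
)
g2 = OrthogroupAlignment(
    "og2",
    {"sp3": "DEDED", "sp4": "DEDED", "sp5": "DE-ED"},
    column_scores=np.array([0.7, 0.7, 0.7, 0.7, 0.7]),
)

masked = [mask_columns(g, threshold=0.5) for g in (g1, g2)]
print("masked lengths:", {g.group_id: g.length for g in masked})

kept = filter_orthogroups(masked, min_taxa_exclusive=2, min_length_exclusive=3)
print("groups kept by the strict filters:", [g.group_id for g in kept])

universe = TaxonUniverse.from_iterable(["sp1", "sp2", "sp3", "sp4", "sp5"])
matrix = concatenate(kept, universe)
print(f"supermatrix: {matrix.n_taxa} taxa x {matrix.columns} columns")
print("partitions:", matrix.partition_lines())
for taxon in matrix.taxa:
    print(f"  {taxon}  {matrix.rows[taxon]}")
print(f"occupancy: {occupancy(matrix):.4f}")
print()
print("og1 loses columns 2 and 4 (scores 0.4, 0.2 < 0.5); absent taxa are")
print("'-' filled, and those cells plus internal gaps count as unoccupied.")
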