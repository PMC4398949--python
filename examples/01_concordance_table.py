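"""Decisive gene counts and congruence frequencies on a toy data set.

A 6-taxon rooted reference tree is tested against three incomplete gene
trees.  For each clade of the reference, the table reports how many gene
trees sample enough taxa to test the clade at all (n_decisive: at least one
taxon from each descendant cluster plus two basal taxa) and what fraction of
those contain the clade's split (congruence_pct).
"""

from phyloconcord import (
    GeneTreeSet,
    TaxonUniverse,
    concordance_table,
    parse_newick,
    rows_to_frame,
)

ref = parse_newick("((A,B),((C,D),(E,F)));")
genes = GeneTreeSet(
    trees=[
        parse_newick("((A,B),(C,E));"),   # supports clade {A,B}
        parse_newick("((A,C),(B,E));"),   # conflicts with clade {A,B}
        parse_newick("((C,D),(E,F));"),   # cannot test {A,B}: no basal taxa
    ],
    names=["gene1", "gene2", "gene3"],
)

rows = concordance_table(ref, genes, TaxonUniverse.from_tree(ref))
print(rows_to_frame(rows).to_string(index=False))
print()
print("Clade A,B: two gene trees are decisive (gene3 samples neither A nor")
print("B), and one of the two contains the A,B split -> 50.0% congruence.")
print("A clade that no gene tree could test would read NA.")
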