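# phyloconcord

Gene-tree concordance counting and supermatrix bookkeeping for
concatenation-based phylogenomics.

## The problem

Phylogenomic data sets built from transcriptomes are incomplete: each gene
tree samples only a subset of the taxa, so a clade of the species tree can
only be tested by the genes that happen to sample it informatively.
`phyloconcord` computes, for every clade of a rooted reference phylogeny,
two numbers over a set of unrooted, partially sampled gene trees:

- **decisive genes** `n_d(C)` — the number of gene trees whose leafset `L`
  satisfies `|L ∩ D₁| ≥ 1`, `|L ∩ D₂| ≥ 1` and `|L ∩ O| ≥ 2`, where `D₁`,
  `D₂` are the clade's two descendant clusters and `O` the taxa basal to it.
  Such a gene spans the internode with minimally a quartet and can therefore
  test the clade at all.
- **congruence frequency** — `100 · n_c(C) / n_d(C)`, where a decisive gene
  counts as congruent iff its unrooted tree contains an edge separating the
  sampled clade members `L ∩ (D₁ ∪ D₂)` from the sampled remainder
  (equivalently, the sampled clade is monophyletic with respect to its
  sampled outgroup).  The count is agnostic to resolution inside the clade
  and inside the outgroup; a polytomy merely *compatible* with the clade is
  not congruent.

Around this statistic the package implements the deterministic accounting of
supermatrix construction — longest-ORF-per-locus selection, confidence-score
column masking (columns `< 0.5` removed, `≥ 0.5` kept), strict orthogroup
inclusion filters (`> 4` taxa and `> 50` masked columns), concatenation over
a taxon universe with partition and occupancy bookkeeping, taxon-deletion
pruning of matrices and gene-tree sets — plus bootstrap clade-frequency
summarization and a fully seeded synthetic-data generator (Yule species
trees, per-gene taxon subsampling, Poisson-distributed NNI noise, random
orthogroup alignments) so that every stage is testable without any external
data.

It is a library first (`import phyloconcord`; see `examples/`), with a thin
`phyloconcord` CLI (`concord`, `support`, `concat`, `mask`, `filter`,
`select-orfs`, `prune`, `simulate`) for shell pipelines.

## Worked example

```python
from phyloconcord import (GeneTreeSet, TaxonUniverse, concordance_table,
                          parse_newick, rows_to_frame)

ref = parse_newick("((A,B),((C,D),(E,F)));")
genes = GeneTreeSet(trees=[parse_newick(s) for s in [
    "((A,B),(C,E));",   # supports clade {A,B}
    "((A,C),(B,E));",   # conflicts with clade {A,B}
    "((C,D),(E,F));",   # samples neither A nor B
]])
rows = concordance_table(ref, genes, TaxonUniverse.from_tree(ref))
print(rows_to_frame(rows).to_string(index=False))
```

prints

```
clade_id clade_taxa  n_genes  n_decisive  n_congruent congruence_pct
   000_A        A,B        3           2            1           50.0
   001_C        C,D        3           1            1          100.0
   002_E        E,F        3           1            1          100.0
   003_C    C,D,E,F        3           2            1           50.0
```

For clade `{A,B}` the first two genes are decisive (each samples A, B and at
least two basal taxa) and only the first contains the `A,B` split, hence
50.0% congruence over 2 decisive genes.  The third gene cannot test that
clade.  A clade with no decisive genes reports `NA`.  `examples/` contains
analogous walk-throughs for bootstrap support, masking/concatenation,
noise sweeps, and taxon-deletion experiments.

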