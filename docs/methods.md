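# Methods

## The concordance statistic

For a rooted binary reference tree over a taxon universe `U`, every internal
non-root node defines a clade `C` with descendant clusters `D₁`, `D₂` (the
leafsets of its two children) and basal set `O = U \ (D₁ ∪ D₂)`.  Given a
gene tree with leafset `L ⊆ U`:

- *Decisive*: `|L ∩ D₁| ≥ 1` and `|L ∩ D₂| ≥ 1` and `|L ∩ O| ≥ 2`.  This is
  the minimal sampling — a quartet spanning the internode — under which the
  gene can bear on the clade.  Gene trees with fewer than four leaves are
  never decisive; no special-casing is needed.
- *Congruent* (evaluated only for decisive genes): the unrooted gene tree
  contains an edge whose split separates `L ∩ (D₁ ∪ D₂)` from
  `L \ (D₁ ∪ D₂)`.  Decisiveness guarantees both sides have ≥ 2 taxa, so the
  split query is always non-trivial.  Internal resolution of the clade and
  of the outgroup is ignored.

The congruence test is equivalent to rooting the gene tree at any sampled
basal leaf and asking whether the sampled clade members are monophyletic;
the test suite checks this equivalence exhaustively on all 15 unrooted
binary 5-leaf topologies (for every 2- and 3-block) and property-tests it on
simulated 12-taxon gene sets.  Two consequences are used as oracles:

- *Perfect-signal law*: if every gene tree is a leaf-subsampled copy of the
  reference topology, congruence is exactly 100% for every clade with at
  least one decisive gene, because pruning preserves all induced splits.
- *Monotonicity*: decisiveness can never be destroyed by sampling more taxa.

Both children of the root are kept as distinct clade definitions even though
they induce the same unrooted split: each carries its own outgroup-facing
counts, matching how internode annotations are displayed on rooted figures.

Polytomy semantics: a polytomy in a gene tree that is merely compatible with
a clade contributes no resolving edge and counts as **not** congruent —
congruence requires positive evidence.  (ML gene trees are binary in
practice, so this choice rarely binds.)

## Bootstrap clade frequencies

`clade_support` takes complete replicate trees (same leafset as the
reference, enforced) and reports, per clade, the percentage of replicates
whose split set contains the clade's unrooted split.  A clade whose split is
trivial on the full leafset (root child facing a single-leaf sibling) is
vacuously present in every replicate and scores 100.

## Supermatrix bookkeeping

- *Longest ORF per locus*: one ORF id per locus — maximum length, ties
  broken by input order (first wins).
- *Masking*: columns with confidence score strictly below the threshold
  (default 0.5) are removed; a score exactly at the threshold is retained,
  reading "below 0.5" literally.  Masking a group to zero length is valid;
  the length filter removes it downstream.
- *Filters*: strict inequalities — more than 4 taxa, more than 50 masked
  columns.  Filtering runs after masking, so the length criterion applies to
  the masked length.
- *Concatenation*: groups are laid down in input order over an ordered taxon
  universe; absent taxa are filled with `-`.  Partitions are 0-based
  half-open internally and emitted 1-based inclusive (RAxML style).
- *Occupancy*: a cell is occupied iff its character is not in
  `{-, ?, X}` (configurable).  Within-sequence alignment gaps therefore
  count as unoccupied, the same as absent-taxon fill — a single unambiguous
  definition; the character set is exposed because archived matrices can
  adjudicate alternatives.
- *Taxon deletion*: removes matrix rows without re-trimming columns (site
  coordinates stay comparable across the experiment) and prunes the same
  taxa from gene trees, discarding trees left with fewer than 4 leaves.
- Taxon names match by exact string comparison; no whitespace munging.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the biology that produces it:

- *Species tree*: pure-birth (Yule) process with unit birth rate, started
  from two lineages; exponential waiting times with rate equal to the
  lineage count; all tips extended to the final time, so trees are exactly
  ultrametric.  Branch lengths are recorded but no statistic uses them.
- *Gene trees*: per gene, a Poisson(`nni_rate`) number of random
  nearest-neighbor interchanges is applied to a copy of the species tree
  (each move picks an internal edge uniformly and one of its two swaps with
  probability 1/2, replacing exactly one split), then each leaf is dropped
  independently with probability `missingness`; genes left with < 4 leaves
  are discarded, counted and logged, not regenerated.
- *Orthogroups*: per gene, a gapless alignment over that gene's surviving
  taxa with uniform random length, i.i.d. uniform residues over the 20
  amino-acid letters, and i.i.d. uniform [0, 1) column scores.

Gene-tree error is modeled as NNI perturbation rather than coalescent
simulation: the target regime is one where apparent incongruence is driven
chiefly by gene-tree estimation error, and NNI counts give direct control of
topological distance from the true tree.  Consequently the generator makes
no claim about incomplete-lineage-sorting signal, substitution processes,
rate heterogeneity, alignment error, or non-random (clade-biased)
missingness — passing tests demonstrate the correctness of the counting
machinery under the stated sampling model, not robustness of inference on
real data.

Defaults are study-scale: 40 taxa, 516 genes, `missingness = 0.5` (giving
roughly half-occupied supermatrices, the regime of transcriptomic data this
targets), `nni_rate = 1.0` (mild estimation error), lengths uniform on
[51, 500] (just above the inclusion filter up to a typical single-gene
alignment).

*Determinism*: every per-gene stream is seeded by the numpy SeedSequence
`[seed, gene_index, stream]`, so outputs are byte-identical across runs and
independent of iteration order.  Topology noise (stream 0) and taxon
subsampling (stream 1) are separated so that sweeps over `nni_rate` at a
fixed seed reuse the identical per-gene missingness pattern — congruence
comparisons across noise levels are paired, which is why the monotone
decline of mean congruence in `nni_rate` can be asserted at Monte-Carlo
sample sizes (500 genes) without additional variance correction.

## Numerical and interface choices

- Rootedness convention: a bifurcating outermost newick node is read as a
  root, a trifurcating one as unrooted (matching common ML-tool output);
  internal-node labels are support strings, never taxa.  The reference tree
  must be rooted and binary; gene trees may contain polytomies.
- Splits are represented as canonicalized pairs of label `frozenset`s — at
  the target scale (≤ a few hundred taxa, hundreds of genes) this is fast
  and keeps every predicate readable; no bitmask encoding is needed.
- Gene-tree taxa absent from the universe are an error by default
  (`unknown_taxon_policy="error"`); `"ignore"` drops them with a logged
  warning.  Silent dropping is never the default because it hides upstream
  label bugs.
- Congruence percentages are reported to one decimal in tables; `NA` marks
  clades with zero decisive genes.
- Problem sizes in the automated checks (16 taxa × 500 genes for the noise
  sweep; 40 taxa × 516 genes for matrix arithmetic; exhaustive enumeration
  at 5 leaves) were chosen as the smallest scales at which the statistical
  assertions have comfortable Monte-Carlo margins (3 standard errors) while
  the whole suite stays interactive.

## Known limitations

- No tree inference, alignment, score computation, or entropy-based
  trimming: those are external tools whose outputs this package consumes.
- The archived-deposit verification (`supermatrix.verify_deposited_matrix`)
  requires a local copy of the study deposit; it is exercised only when one
  is present.
- NNI-perturbed trees keep their original branch lengths on rearranged
  subtrees; lengths are carried, not modeled.
- `clade_support` requires complete replicates; summarizing incomplete
  bootstrap trees is out of scope.
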