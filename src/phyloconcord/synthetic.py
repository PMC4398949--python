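"""Synthetic species trees, incomplete noisy gene trees, and orthogroups.

The generator emulates the statistical structure a concatenation +
gene-tree-concordance analysis assumes: a rooted binary species tree (Yule
process), per-gene taxon subsampling (each taxon missing from each gene
independently, matching the roughly half-empty occupancy typical of
transcriptome supermatrices), per-gene topological error modeled as a
Poisson-distributed number of random nearest-neighbor-interchange (NNI)
moves, and orthogroup alignments of varying length with random residues and
column scores.

Everything is deterministic given a :class:`SimulationConfig`: per-gene
random streams are derived from ``(seed, gene_index, stream)`` seed
sequences, so outputs do not depend on iteration order and the taxon-sampling
pattern of gene *i* is identical across runs that differ only in
``nni_rate`` — useful for paired comparisons across noise levels.

No sequence evolution is simulated: residues are i.i.d. noise, adequate for
testing bookkeeping (occupancy, masking, concatenation) but carrying no
phylogenetic signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .concordance import GeneTreeSet
from .trees import TaxonUniverse, TreeValidationError, leaf_labels, restrict_to_taxa
from .supermatrix import OrthogroupAlignment

__all__ = [
    "SimulationConfig",
    "enumerate_topologies",
    "simulate_yule_tree",
    "subsample_leaves",
    "perturb_nni",
    "simulate_gene_tree_set",
    "simulate_orthogroups",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 40 taxa, 516 genes, ~50% missingness.

    ``missingness`` is the independent per-taxon per-gene drop probability;
    at 0.5 the expected supermatrix occupancy is ~50%, matching the
    half-empty transcriptomic matrices this package targets.  ``nni_rate`` is
    the expected number of NNI perturbations per gene tree (Poisson count);
    1.0 gives mild, realistic gene-tree estimation error.  ``length_range``
    spans orthogroup lengths just above the 50-column inclusion filter up to
    a typical single-gene alignment length.
    """

    n_taxa: int = 40
    n_genes: int = 516
    missingness: float = 0.5
    nni_rate: float = 1.0
    length_range: tuple[int, int] = (51, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        if self.nni_rate < 0:
            raise ValueError("nni_rate must be non-negative")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("length_range must satisfy 1 <= min <= max")


def enumerate_topologies(labels: Sequence[str]) -> list[dendropy.Tree]:
    """Every unrooted binary topology on ``labels`` — (2n-5)!! trees.

    Built by inserting each successive leaf on every edge of every smaller
    topology; feasible only for small n (15 trees at n=5, 105 at n=6).
    Useful for exhaustive checks of split predicates.
    """
    from .trees import parse_newick

    if len(labels) < 3:
        raise ValueError("need at least 3 labels for an unrooted topology")

    def rooted_shapes(lbls):
        if len(lbls) == 1:
            return [lbls[0]]
        shapes = []
        for shape in rooted_shapes(lbls[:-1]):
            shapes.extend(insertions(shape, lbls[-1]))
        return shapes

    def insertions(shape, leaf):
        out = [(shape, leaf)]
        if isinstance(shape, tuple):
            left, right = shape
            out += [(new, right) for new in insertions(left, leaf)]
            out += [(left, new) for new in insertions(right, leaf)]
        return out

    def render(shape):
        if isinstance(shape, str):
            return shape
        return f"({render(shape[0])},{render(shape[1])})"

    first, rest = labels[0], list(labels[1:])
    return [
        parse_newick(f"({render(l)},{render(r)},{first});")
        for l, r in rooted_shapes(rest)
    ]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_yule_tree(n_taxa: int, seed: int | np.random.Generator) -> dendropy.Tree:
    """Rooted binary ultrametric tree from a pure-birth (Yule) process.

    Starting from two lineages, waiting times to the next speciation are
    exponential with rate equal to the current lineage count (unit birth
    rate); the lineage that splits is chosen uniformly.  All leaves end at
    the same final time, so root-to-tip path lengths are exactly equal.
    Leaves are labeled ``t1..tn`` in preorder.
    """
    if n_taxa < 2:
        raise ValueError("a Yule tree needs at least 2 taxa")
    rng = _rng(seed)
    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, _birth = active.pop(i)
        node.edge.length = t - _birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    end = t + rng.exponential(1.0 / n_taxa)
    for node, birth in active:
        node.edge.length = end - birth
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            counter += 1
            node.taxon = ns.require_taxon(f"t{counter}")
    tree.is_rooted = True
    return tree


def subsample_leaves(
    tree: dendropy.Tree,
    missingness: float,
    seed: int | np.random.Generator = 0,
) -> Optional[dendropy.Tree]:
    """Drop each leaf independently with probability ``missingness``.

    Degree-2 nodes are suppressed, so the surviving tree's splits are exactly
    the restriction of the original's.  Returns None (a discard marker) if
    fewer than four leaves survive — such a tree can test no clade.
    """
    if not 0.0 <= missingness < 1.0:
        raise ValueError("missingness must be in [0, 1)")
    rng = _rng(seed)
    labels = sorted(leaf_labels(tree))
    keep = [l for l in labels if rng.random() >= missingness]
    if len(keep) < 4:
        return None
    return restrict_to_taxa(tree, keep)


def _nni_candidates(t: dendropy.Tree) -> list[dendropy.Node]:
    """Child endpoints of internal edges, in the leaf-rooted frame.

    With the tree rooted on a pendant edge, each internal edge of the
    underlying unrooted tree is exactly one parent->child edge between two
    non-seed internal nodes; we return the child ends in preorder.
    """
    out = []
    for node in t.preorder_internal_node_iter():
        parent = node.parent_node
        if parent is None or parent is t.seed_node:
            continue
        if not parent.is_leaf():
            out.append(node)
    return out


def perturb_nni(
    tree: dendropy.Tree,
    k: int,
    seed: int | np.random.Generator = 0,
) -> dendropy.Tree:
    """Apply ``k`` random nearest-neighbor interchanges to a copy of ``tree``.

    Each move picks an internal edge of the unrooted tree uniformly at random
    and performs one of its two subtree swaps with probability 1/2; a single
    move therefore replaces exactly one split.  The leafset never changes.
    Requires a binary tree (interpreting a bifurcating root as unrooted) with
    at least one internal edge.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = _rng(seed)
    labels = sorted(leaf_labels(tree))
    if len(labels) < 4:
        raise TreeValidationError("NNI needs at least 4 leaves")
    # Work rooted at the first leaf so every unrooted internal edge is one
    # parent->child edge between internal nodes.
    t = tree.clone(depth=1)
    anchor = next(lf for lf in t.leaf_node_iter() if lf.taxon.label == labels[0])
    t.reroot_at_edge(anchor.edge, update_bipartitions=False)
    t.suppress_unifurcations()
    for node in t.preorder_internal_node_iter():
        nch = len(node.child_nodes())
        expected = 2
        if nch != expected:
            raise TreeValidationError("NNI perturbation requires a binary tree")
    for _ in range(k):
        candidates = _nni_candidates(t)
        if not candidates:
            raise TreeValidationError("tree has no internal edge to perturb")
        child = candidates[int(rng.integers(len(candidates)))]
        parent = child.parent_node
        sibling = next(c for c in parent.child_nodes() if c is not child)
        grandkids = child.child_nodes()
        swap_in = grandkids[int(rng.integers(2))]
        child.remove_child(swap_in)
        parent.remove_child(sibling)
        child.add_child(sibling)
        parent.add_child(swap_in)
    t.is_rooted = False
    return t


def simulate_gene_tree_set(
    species_tree: dendropy.Tree, config: SimulationConfig
) -> GeneTreeSet:
    """Per-gene: Poisson(nni_rate) NNI moves, then leaf subsampling.

    Gene *i* draws its topology noise from stream ``(seed, i, 0)`` and its
    taxon sampling from stream ``(seed, i, 1)``.  Genes left with fewer than
    four leaves are discarded (counted in ``n_discarded``, logged, not
    regenerated), so the realized set may be smaller than requested.
    """
    n_sp = len(leaf_labels(species_tree))
    if n_sp != config.n_taxa:
        raise ValueError(
            f"species tree has {n_sp} leaves but config.n_taxa={config.n_taxa}"
        )
    trees, names, discarded = [], [], 0
    for i in range(config.n_genes):
        rng_topo = np.random.default_rng([config.seed, i, 0])
        rng_sample = np.random.default_rng([config.seed, i, 1])
        k = int(rng_topo.poisson(config.nni_rate)) if config.nni_rate > 0 else 0
        gene = (
            perturb_nni(species_tree, k, rng_topo) if k > 0
            else species_tree.clone(depth=1)
        )
        gene = subsample_leaves(gene, config.missingness, rng_sample)
        if gene is None:
            discarded += 1
            continue
        gene.is_rooted = False
        trees.append(gene)
        names.append(f"g{i:04d}")
    if discarded:
        logger.info(
            "simulate_gene_tree_set: discarded %d of %d genes (<4 leaves)",
            discarded, config.n_genes,
        )
    return GeneTreeSet(trees=trees, names=names, n_discarded=discarded)


def simulate_orthogroups(
    species: TaxonUniverse,
    presence: Sequence[frozenset[str] | set[str]],
    length_range: tuple[int, int] = (51, 500),
    seed: int = 0,
) -> list[OrthogroupAlignment]:
    """One gapless random alignment per gene over the given presence sets.

    Lengths are uniform over ``length_range`` (inclusive); residues are
    i.i.d. uniform over the 20 amino-acid letters; column scores are i.i.d.
    uniform on [0, 1].  Deterministic per ``(seed, gene index)``.
    """
    uni = species.as_set()
    lo, hi = length_range
    groups = []
    for i, taxa in enumerate(presence):
        taxa = frozenset(taxa)
        if not taxa <= uni:
            raise TreeValidationError(
                f"gene {i}: presence taxa outside universe: {sorted(taxa - uni)}"
            )
        rng = np.random.default_rng([seed, i, 2])
        L = int(rng.integers(lo, hi + 1))
        aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
        seqs = {}
        for taxon in sorted(taxa):
            idx = rng.integers(0, len(AMINO_ACIDS), size=L)
            seqs[taxon] = aa[idx].tobytes().decode()
        groups.append(
            OrthogroupAlignment(
                group_id=f"OG{i:04d}",
                sequences=seqs,
                column_scores=rng.random(L),
            )
        )
    return groups


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dendropy.Tree, GeneTreeSet, list[OrthogroupAlignment]]:
    """Full synthetic study: species tree, gene trees, matching orthogroups.

    Orthogroup presence sets are the gene trees' leafsets, so the gene-tree
    and supermatrix views of the data agree taxon-for-taxon.
    """
    species_tree = simulate_yule_tree(config.n_taxa, np.random.default_rng([config.seed, 1000003]))
    genes = simulate_gene_tree_set(species_tree, config)
    universe = TaxonUniverse.from_tree(species_tree)
    presence = [leaf_labels(t) for t in genes.trees]
    groups = simulate_orthogroups(
        universe, presence, length_range=config.length_range, seed=config.seed
    )
    for aln, name in zip(groups, genes.names or []):
        aln.group_id = name
    return species_tree, genes, groups
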