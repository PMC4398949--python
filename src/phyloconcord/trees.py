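"""Newick I/O and the bipartition / monophyly engine.

Trees are :class:`dendropy.Tree` objects, validated on entry.  Rootedness
follows the convention of most ML software output: a newick statement whose
outermost node is bifurcating is read as rooted, a trifurcating (or higher)
one as unrooted.  Internal-node labels are always treated as support strings,
never as taxon names.  Branch lengths are carried through I/O but no statistic
in this package uses them.

All split operations work on plain ``frozenset`` blocks of taxon labels, which
is fast enough for the tree sizes this package targets (tens to low hundreds
of taxa) and keeps every predicate transparent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "TaxonUniverse",
    "Bipartition",
    "CladeDefinition",
    "parse_newick",
    "parse_newick_list",
    "read_trees",
    "write_newick",
    "leaf_labels",
    "tree_splits",
    "has_split",
    "extract_clade_definitions",
    "reroot_at_leaf",
    "is_monophyletic",
    "restrict_to_taxa",
]


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced parentheses, missing ';', ...)."""


class TreeValidationError(ValueError):
    """Structurally valid newick that violates a package invariant."""


@dataclass(frozen=True)
class TaxonUniverse:
    """Ordered set of unique taxon labels; the index space for all splits.

    The label order is fixed at construction and stable for the lifetime of
    the object, so positions can serve as bit indices if a caller wants a
    bitmask encoding.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.labels:
            raise TreeValidationError("taxon universe must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise TreeValidationError(f"duplicate taxon labels in universe: {dupes}")

    @classmethod
    def from_iterable(cls, labels: Iterable[str]) -> "TaxonUniverse":
        return cls(tuple(labels))

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "TaxonUniverse":
        """Universe from a tree's leaves, in alphabetical order."""
        return cls(tuple(sorted(leaf_labels(tree))))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    @property
    def _index(self) -> dict[str, int]:
        # cached lazily on the instance despite frozen=True
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {l: i for i, l in enumerate(self.labels)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def index(self, label: str) -> int:
        return self._index[label]

    def as_set(self) -> frozenset[str]:
        return frozenset(self.labels)

    def subset(self, labels: Iterable[str]) -> frozenset[str]:
        """Validated subset; raises if any label is foreign."""
        sub = frozenset(labels)
        extra = sub - self.as_set()
        if extra:
            raise TreeValidationError(f"labels not in universe: {sorted(extra)}")
        return sub


@dataclass(frozen=True)
class Bipartition:
    """A split of a leafset into two non-empty blocks.

    Canonical orientation: ``block_a`` is the block containing the
    alphabetically first label of the full leafset (the "first present taxon"
    under the universe ordering used throughout, which is alphabetical for
    tree-local splits).  Equality and hashing use the blocks only.
    """

    block_a: frozenset[str]
    block_b: frozenset[str]
    universe: Optional[TaxonUniverse] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        a, b = frozenset(self.block_a), frozenset(self.block_b)
        if not a or not b:
            raise TreeValidationError("bipartition blocks must be non-empty")
        if a & b:
            raise TreeValidationError(f"bipartition blocks overlap: {sorted(a & b)}")
        first = self._first_label(a | b)
        if first in b:
            a, b = b, a
        object.__setattr__(self, "block_a", a)
        object.__setattr__(self, "block_b", b)

    def _first_label(self, leafset: frozenset[str]) -> str:
        if self.universe is not None:
            present = [l for l in self.universe.labels if l in leafset]
            if present:
                return present[0]
        return min(leafset)

    @property
    def leafset(self) -> frozenset[str]:
        return self.block_a | self.block_b

    def is_trivial(self) -> bool:
        return min(len(self.block_a), len(self.block_b)) < 2

    def restricted(self, keep: frozenset[str]) -> Optional["Bipartition"]:
        """The induced split on ``keep``, or None if it becomes trivial."""
        a, b = self.block_a & keep, self.block_b & keep
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition(a, b)

    def __str__(self) -> str:
        return "{}|{}".format(
            ",".join(sorted(self.block_a)), ",".join(sorted(self.block_b))
        )


@dataclass(frozen=True)
class CladeDefinition:
    """A focal rooted clade: two descendant clusters and the basal remainder.

    ``d1``/``d2`` are the leafsets of the two children of an internal node of
    the rooted reference tree (in parse order; the statistics below are
    symmetric in them) and ``outgroup`` is every universe taxon outside the
    clade.
    """

    clade_id: str
    d1: frozenset[str]
    d2: frozenset[str]
    outgroup: frozenset[str]

    def __post_init__(self) -> None:
        if not self.d1 or not self.d2:
            raise TreeValidationError("descendant clusters must be non-empty")
        if self.d1 & self.d2 or self.d1 & self.outgroup or self.d2 & self.outgroup:
            raise TreeValidationError("clade blocks must be pairwise disjoint")

    @property
    def clade_taxa(self) -> frozenset[str]:
        return self.d1 | self.d2

    @property
    def universe_set(self) -> frozenset[str]:
        return self.d1 | self.d2 | self.outgroup


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single newick statement into a validated tree.

    Leaf labels, branch lengths and internal-node labels (support values)
    are preserved, as are polytomies.  A bifurcating outermost node marks the
    tree as rooted; a trifurcating one as unrooted.

    Raises
    ------
    NewickParseError
        On malformed newick (the message carries dendropy's line/column).
    TreeValidationError
        On duplicate leaf labels.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"newick statement must end in ';' (got ...{stripped[-10:]!r})"
        )
    try:
        tree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "Duplicate taxon" in msg or "Multiple occurrences" in msg:
            raise TreeValidationError(f"duplicate leaf label: {msg}") from None
        raise NewickParseError(msg) from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeValidationError(f"duplicate leaf label(s): {dupes}")
    if any(lf.taxon is None for lf in tree.leaf_node_iter()):
        raise TreeValidationError("unlabeled leaf in newick input")
    tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    return tree


def parse_newick_list(text: str) -> list[dendropy.Tree]:
    """Parse a multi-tree newick string, one statement per line."""
    trees = []
    for line in text.splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line))
    return trees


def read_trees(path: str) -> list[dendropy.Tree]:
    """Read a newick file with one tree per line."""
    with open(path) as fh:
        return parse_newick_list(fh.read())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single newick statement.

    Round-trip guarantee: parsing the output yields a tree with identical
    leafset, split set and branch lengths (to printed precision).
    """
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


# ---------------------------------------------------------------------------
# Split algebra


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _node_leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset((node.taxon.label,))
        else:
            sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
    return sets


def tree_splits(tree: dendropy.Tree) -> frozenset[Bipartition]:
    """The non-trivial splits (both blocks >= 2) induced by internal edges.

    Rooted trees are read as their unrooted equivalent: the two edges at a
    bifurcating root induce the same split, which is counted once.  Trees with
    fewer than four leaves have no non-trivial split and yield the empty set.
    """
    all_leaves = leaf_labels(tree)
    n = len(all_leaves)
    if n < 4:
        return frozenset()
    sets = _node_leafsets(tree)
    splits = set()
    for node in tree.postorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        block = sets[node]
        if 2 <= len(block) <= n - 2:
            splits.add(Bipartition(block, all_leaves - block))
    return frozenset(splits)


def has_split(tree: dendropy.Tree, block: Iterable[str]) -> bool:
    """True iff some edge of the unrooted tree separates exactly ``block``.

    ``block`` must be a proper subset of the leafset with
    ``2 <= |block| <= n - 2``; trivial block sizes are rejected because every
    pendant edge realizes them vacuously.
    """
    block = frozenset(block)
    leaves = leaf_labels(tree)
    if not block <= leaves:
        raise TreeValidationError(
            f"block contains taxa absent from the tree: {sorted(block - leaves)}"
        )
    if not 2 <= len(block) <= len(leaves) - 2:
        raise TreeValidationError(
            f"block size {len(block)} is trivial for a {len(leaves)}-leaf tree"
        )
    return Bipartition(block, leaves - block) in tree_splits(tree)


def reroot_at_leaf(tree: dendropy.Tree, leaf: str) -> dendropy.Tree:
    """A copy of ``tree`` rooted on the pendant edge of ``leaf``.

    The unrooted split set is unchanged; the result is a convenient frame for
    monophyly queries against taxa outside a focal block.
    """
    t = tree.clone(depth=1)
    node = next(
        (lf for lf in t.leaf_node_iter() if lf.taxon.label == leaf), None
    )
    if node is None:
        raise TreeValidationError(f"leaf {leaf!r} not in tree")
    t.reroot_at_edge(node.edge, update_bipartitions=False)
    t.suppress_unifurcations()
    t.is_rooted = True
    return t


def is_monophyletic(rooted: dendropy.Tree, block: Iterable[str]) -> bool:
    """True iff some node of the rooted tree has exactly ``block`` below it."""
    block = frozenset(block)
    if not block:
        raise TreeValidationError("monophyly query on an empty block")
    leaves = leaf_labels(rooted)
    if not block <= leaves:
        raise TreeValidationError(
            f"block contains taxa absent from the tree: {sorted(block - leaves)}"
        )
    sets = _node_leafsets(rooted)
    return any(s == block for s in sets.values())


def _assert_rooted_binary(ref: dendropy.Tree) -> None:
    if len(ref.seed_node.child_nodes()) != 2:
        raise TreeValidationError(
            "reference tree is unrooted (trifurcating base); root it first"
        )
    for node in ref.preorder_node_iter():
        nch = len(node.child_nodes())
        if nch not in (0, 2):
            raise TreeValidationError(
                "reference tree has a polytomy; resolve it before extracting clades"
            )


def extract_clade_definitions(
    ref: dendropy.Tree, universe: TaxonUniverse
) -> list[CladeDefinition]:
    """One CladeDefinition per internal non-root node of a rooted binary tree.

    ``d1``/``d2`` are the child leafsets in parse order and the outgroup is
    the universe complement.  Clade ids combine the node's post-order index
    with the smallest contained taxon label, which is stable across runs.

    The two children of the root describe the same unrooted split but are kept
    as distinct definitions, each with its own outgroup-facing statistics.
    """
    _assert_rooted_binary(ref)
    uni = universe.as_set()
    if leaf_labels(ref) != uni:
        raise TreeValidationError(
            "reference tree leafset does not equal the taxon universe"
        )
    sets = _node_leafsets(ref)
    defs = []
    for idx, node in enumerate(ref.postorder_internal_node_iter()):
        if node is ref.seed_node:
            continue
        c1, c2 = node.child_nodes()
        d1, d2 = sets[c1], sets[c2]
        clade = d1 | d2
        defs.append(
            CladeDefinition(
                clade_id=f"{idx:03d}_{min(clade)}",
                d1=d1,
                d2=d2,
                outgroup=uni - clade,
            )
        )
    return defs


def restrict_to_taxa(
    tree: dendropy.Tree, keep: Iterable[str]
) -> Optional[dendropy.Tree]:
    """A copy of ``tree`` restricted to ``keep`` (degree-2 nodes suppressed).

    Returns None if fewer than two of the requested taxa are present (no tree
    remains).  Pruning preserves every induced split.
    """
    keep = frozenset(keep)
    present = leaf_labels(tree) & keep
    if len(present) < 2:
        return None
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(present))
    t.suppress_unifurcations()
    t.is_rooted = len(t.seed_node.child_nodes()) == 2
    return t
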