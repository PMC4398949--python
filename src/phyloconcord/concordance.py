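"""Per-clade decisive gene counts and congruence frequencies.

The statistic: for every internal node (clade) of a rooted reference tree,
count the gene trees whose taxon sampling permits testing that clade at all
(*decisive*: at least one taxon sampled from each of the clade's two
descendant clusters, plus at least two taxa basal to the node — minimally a
quartet), and among those, count the gene trees that actually *support* the
clade (*congruent*: the sampled clade members form one side of some edge of
the unrooted gene tree).  Congruence is agnostic to the resolution inside the
clade and inside the outgroup.

Also here: bootstrap clade-frequency summarization over replicate tree sets,
and annotation of the reference tree with the computed numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

from .trees import (
    Bipartition,
    CladeDefinition,
    TaxonUniverse,
    TreeValidationError,
    extract_clade_definitions,
    leaf_labels,
    restrict_to_taxa,
    tree_splits,
    write_newick,
)

__all__ = [
    "GeneTreeSet",
    "ConcordanceRow",
    "is_decisive",
    "is_congruent",
    "concordance_table",
    "rows_to_frame",
    "clade_support",
    "annotate_reference",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneTreeSet:
    """A collection of (possibly incomplete, unrooted) gene trees."""

    trees: list[dendropy.Tree]
    names: Optional[list[str]] = None
    n_discarded: int = 0

    def __post_init__(self) -> None:
        if self.names is not None and len(self.names) != len(self.trees):
            raise ValueError("names and trees must have equal length")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        names = self.names or [f"g{i:04d}" for i in range(len(self.trees))]
        return iter(zip(self.trees, names))


@dataclass(frozen=True)
class ConcordanceRow:
    """Counts for one clade of the reference tree.

    ``congruence_pct`` is ``100 * n_congruent / n_decisive`` when any gene is
    decisive, else None (reported as "NA").
    """

    clade_id: str
    clade_taxa: frozenset[str]
    n_genes: int
    n_decisive: int
    n_congruent: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_congruent <= self.n_decisive <= self.n_genes:
            raise ValueError(
                f"invalid counts for {self.clade_id}: "
                f"{self.n_congruent} <= {self.n_decisive} <= {self.n_genes} violated"
            )

    @property
    def congruence_pct(self) -> Optional[float]:
        if self.n_decisive == 0:
            return None
        return 100.0 * self.n_congruent / self.n_decisive


def is_decisive(gene_leafset: Iterable[str], clade: CladeDefinition) -> bool:
    """Can this gene's taxon sampling test the clade at all?

    Requires at least one sampled taxon in each descendant cluster and at
    least two sampled basal taxa, so that minimally a quartet spans the
    internode.  Gene trees with fewer than four leaves are therefore never
    decisive for any clade.
    """
    ls = frozenset(gene_leafset)
    return (
        len(ls & clade.d1) >= 1
        and len(ls & clade.d2) >= 1
        and len(ls & clade.outgroup) >= 2
    )


def is_congruent(
    gene_tree: dendropy.Tree,
    clade: CladeDefinition,
    *,
    gene_leafset: Optional[frozenset[str]] = None,
    gene_splits: Optional[frozenset[Bipartition]] = None,
) -> bool:
    """Does a decisive gene tree contain the clade's split?

    True iff the sampled clade members form one side of some edge of the
    unrooted gene tree — i.e. they are monophyletic with respect to the
    sampled outgroup.  A polytomy that is merely compatible with the clade
    (no resolving edge) counts as NOT congruent: congruence demands positive
    evidence.

    Must only be called on decisive gene trees; ``gene_leafset`` and
    ``gene_splits`` may be supplied to reuse precomputed values.
    """
    ls = gene_leafset if gene_leafset is not None else leaf_labels(gene_tree)
    if not is_decisive(ls, clade):
        raise TreeValidationError(
            f"is_congruent called on a gene tree that is not decisive for "
            f"clade {clade.clade_id}; gate on is_decisive first"
        )
    sampled_clade = ls & clade.clade_taxa
    splits = gene_splits if gene_splits is not None else tree_splits(gene_tree)
    return Bipartition(sampled_clade, ls - sampled_clade) in splits


def _prepare_genes(
    genes: GeneTreeSet,
    universe: TaxonUniverse,
    unknown_taxon_policy: str,
) -> list[tuple[frozenset[str], frozenset[Bipartition]]]:
    uni = universe.as_set()
    prepared = []
    for tree, name in genes:
        ls = leaf_labels(tree)
        foreign = ls - uni
        if foreign:
            if unknown_taxon_policy == "error":
                raise TreeValidationError(
                    f"gene tree {name!r} has taxa outside the universe: "
                    f"{sorted(foreign)} (use policy='ignore' to drop them)"
                )
            elif unknown_taxon_policy == "ignore":
                logger.warning(
                    "gene tree %s: dropping %d leaves outside the universe: %s",
                    name, len(foreign), sorted(foreign),
                )
                pruned = restrict_to_taxa(tree, ls & uni)
                if pruned is None:
                    prepared.append((ls & uni, frozenset()))
                    continue
                tree, ls = pruned, leaf_labels(pruned)
            else:
                raise ValueError(
                    f"unknown_taxon_policy must be 'error' or 'ignore', "
                    f"got {unknown_taxon_policy!r}"
                )
        prepared.append((ls, tree_splits(tree)))
    return prepared


def concordance_table(
    ref: dendropy.Tree,
    genes: GeneTreeSet,
    universe: TaxonUniverse,
    unknown_taxon_policy: str = "error",
) -> list[ConcordanceRow]:
    """Decisive and congruent gene counts for every clade of the reference.

    One row per internal non-root node of the rooted binary reference tree.
    Deterministic given its inputs.  Gene-tree taxa outside the universe are
    an error by default; ``unknown_taxon_policy='ignore'`` drops them with a
    logged warning instead.
    """
    clades = extract_clade_definitions(ref, universe)
    prepared = _prepare_genes(genes, universe, unknown_taxon_policy)
    rows = []
    for clade in clades:
        n_dec = n_con = 0
        for ls, splits in prepared:
            if not is_decisive(ls, clade):
                continue
            n_dec += 1
            sampled = ls & clade.clade_taxa
            if Bipartition(sampled, ls - sampled) in splits:
                n_con += 1
        rows.append(
            ConcordanceRow(
                clade_id=clade.clade_id,
                clade_taxa=clade.clade_taxa,
                n_genes=len(genes),
                n_decisive=n_dec,
                n_congruent=n_con,
            )
        )
    return rows


def _fmt_pct(pct: Optional[float]) -> str:
    return "NA" if pct is None else f"{pct:.1f}"


def rows_to_frame(rows: Sequence[ConcordanceRow]) -> pd.DataFrame:
    """Tabulate concordance rows (clade taxa comma-joined and sorted)."""
    return pd.DataFrame(
        {
            "clade_id": [r.clade_id for r in rows],
            "clade_taxa": [",".join(sorted(r.clade_taxa)) for r in rows],
            "n_genes": [r.n_genes for r in rows],
            "n_decisive": [r.n_decisive for r in rows],
            "n_congruent": [r.n_congruent for r in rows],
            "congruence_pct": [_fmt_pct(r.congruence_pct) for r in rows],
        }
    )


def clade_support(
    ref: dendropy.Tree, replicates: Sequence[dendropy.Tree]
) -> dict[str, float]:
    """Bootstrap support: % of replicate trees containing each clade's split.

    Every replicate must carry exactly the reference leafset (bootstrap
    replicates are complete by construction).  Clades whose unrooted split is
    trivial (a root child facing a single-leaf sibling) are present in every
    tree and score 100.
    """
    universe = TaxonUniverse.from_tree(ref)
    uni = universe.as_set()
    n = len(uni)
    clades = extract_clade_definitions(ref, universe)
    rep_splits = []
    for i, rep in enumerate(replicates):
        rls = leaf_labels(rep)
        if rls != uni:
            missing, extra = sorted(uni - rls), sorted(rls - uni)
            raise TreeValidationError(
                f"replicate {i} leafset mismatch (missing {missing}, extra {extra})"
            )
        rep_splits.append(tree_splits(rep))
    out = {}
    for clade in clades:
        block = clade.clade_taxa
        if not 2 <= len(block) <= n - 2:
            out[clade.clade_id] = 100.0
            continue
        split = Bipartition(block, uni - block)
        hits = sum(split in s for s in rep_splits)
        out[clade.clade_id] = 100.0 * hits / len(replicates) if replicates else 0.0
    return out


def annotate_reference(
    ref: dendropy.Tree,
    rows: Sequence[ConcordanceRow],
    supports: Optional[Mapping[str, float]] = None,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Label each internal node of a copy of ``ref`` with its statistics.

    Node labels read ``congruence_pct|n_decisive`` (plus ``|support`` when a
    support map is given); NA congruence renders as "NA".  Labels survive a
    newick round-trip.  Returns the annotated tree and the full table.
    """
    by_id = {r.clade_id: r for r in rows}
    universe = TaxonUniverse.from_tree(ref)
    clades = extract_clade_definitions(ref, universe)
    known = {c.clade_id for c in clades}
    unknown = set(by_id) - known
    if unknown:
        raise TreeValidationError(
            f"rows reference clade ids absent from the tree: {sorted(unknown)}"
        )
    if supports is not None and set(supports) - known:
        raise TreeValidationError(
            f"supports reference clade ids absent from the tree: "
            f"{sorted(set(supports) - known)}"
        )
    annotated = ref.clone(depth=1)
    idx = 0
    for node in annotated.postorder_internal_node_iter():
        if node is annotated.seed_node:
            continue
        clade_id = clades[idx].clade_id
        idx += 1
        row = by_id.get(clade_id)
        if row is None:
            continue
        label = f"{_fmt_pct(row.congruence_pct)}|{row.n_decisive}"
        if supports is not None and clade_id in supports:
            label += f"|{supports[clade_id]:.1f}"
        node.label = label
    frame = rows_to_frame(rows)
    if supports is not None:
        frame["support_pct"] = [
            f"{supports[r.clade_id]:.1f}" if r.clade_id in supports else "NA"
            for r in rows
        ]
    return annotated, frame
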