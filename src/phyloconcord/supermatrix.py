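"""Supermatrix construction bookkeeping.

Covers the deterministic accounting steps of a concatenation-based
phylogenomic pipeline: keeping the longest ORF per assembly locus, masking
alignment columns below a confidence threshold, filtering orthogroups on
taxon count and masked length, concatenating orthogroup alignments over a
common taxon universe with occupancy accounting, and the pruning operations
used in taxon-deletion experiments.

Alignment computation, column-score computation and entropy-based trimming
are upstream/external concerns: scores are consumed here, never produced.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .concordance import GeneTreeSet
from .trees import TaxonUniverse, TreeValidationError, leaf_labels, restrict_to_taxa

__all__ = [
    "OrfRecord",
    "OrthogroupAlignment",
    "Supermatrix",
    "select_longest_per_locus",
    "mask_columns",
    "filter_orthogroups",
    "concatenate",
    "occupancy",
    "occupancy_report",
    "delete_taxa_matrix",
    "prune_gene_trees",
    "read_orthogroup_fasta",
    "read_column_scores",
    "read_orthogroup_dir",
    "write_orthogroup_fasta",
    "verify_deposited_matrix",
]

logger = logging.getLogger(__name__)

#: characters that do not count as an observed residue
DEFAULT_UNOCCUPIED = frozenset({"-", "?", "X"})


@dataclass(frozen=True)
class OrfRecord:
    """One predicted open reading frame from one assembly subcomponent."""

    locus_id: str
    orf_id: str
    length: int
    rank: int = 0  # input-order index, used only to break length ties

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"ORF {self.orf_id}: length must be >= 1")


def select_longest_per_locus(records: Sequence[OrfRecord]) -> set[str]:
    """Keep exactly one ORF id per locus: the longest, first-seen on ties.

    This is the redundancy-reduction rule applied to per-locus ORF
    predictions before orthology assignment.
    """
    best: dict[str, OrfRecord] = {}
    for rank, rec in enumerate(records):
        rec = replace(rec, rank=rank)
        cur = best.get(rec.locus_id)
        if cur is None or rec.length > cur.length:
            best[rec.locus_id] = rec
    return {rec.orf_id for rec in best.values()}


@dataclass
class OrthogroupAlignment:
    """One aligned orthogroup: at most one sequence per taxon, uniform length.

    ``column_scores`` (when present) hold one alignment-confidence value in
    [0, 1] per column, as produced by pair-HMM certainty tools.
    """

    group_id: str
    sequences: dict[str, str]
    column_scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"orthogroup {self.group_id}: unequal sequence lengths {sorted(lengths)}"
            )
        if self.column_scores is not None:
            self.column_scores = np.asarray(self.column_scores, dtype=float)
            if self.column_scores.shape != (self.length,):
                raise ValueError(
                    f"orthogroup {self.group_id}: {self.column_scores.size} scores "
                    f"for {self.length} columns"
                )

    @property
    def length(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.sequences)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)


def mask_columns(aln: OrthogroupAlignment, threshold: float = 0.5) -> OrthogroupAlignment:
    """Drop alignment columns whose confidence score is below ``threshold``.

    Columns scoring exactly the threshold are retained (only strictly-below
    scores are removed).  Column order is preserved and the score vector is
    subset in step.  A zero-length result is valid — it will fall to the
    length filter downstream.
    """
    if aln.column_scores is None:
        raise ValueError(f"orthogroup {aln.group_id}: no column scores to mask on")
    keep = np.flatnonzero(aln.column_scores >= threshold)
    seqs = {
        taxon: "".join(seq[i] for i in keep) for taxon, seq in aln.sequences.items()
    }
    return OrthogroupAlignment(
        group_id=aln.group_id,
        sequences=seqs,
        column_scores=aln.column_scores[keep],
    )


def filter_orthogroups(
    groups: Iterable[OrthogroupAlignment],
    min_taxa_exclusive: int = 4,
    min_length_exclusive: int = 50,
) -> list[OrthogroupAlignment]:
    """Keep groups with strictly more taxa / columns than the cutoffs.

    Defaults encode the usual inclusion criteria for concatenation: more than
    four species and a masked length greater than 50 amino acids.  Both bounds
    are exclusive, so a 4-taxon or 50-column group is dropped.
    """
    return [
        g
        for g in groups
        if g.n_taxa > min_taxa_exclusive and g.length > min_length_exclusive
    ]


@dataclass
class Supermatrix:
    """Concatenated character matrix over an ordered taxon set.

    ``partitions`` are (group_id, start, end) spans, 0-based half-open, in
    concatenation order; they tile [0, columns) exactly.  Emitted partition
    files use 1-based inclusive coordinates (RAxML style).
    """

    taxa: tuple[str, ...]
    rows: dict[str, str]
    partitions: tuple[tuple[str, int, int], ...]
    fill_char: str = "-"

    def __post_init__(self) -> None:
        if set(self.rows) != set(self.taxa):
            raise ValueError("row keys must equal the taxon list")
        ncol = self.columns
        for taxon in self.taxa:
            if len(self.rows[taxon]) != ncol:
                raise ValueError(
                    f"row {taxon!r} has {len(self.rows[taxon])} columns, expected {ncol}"
                )
        pos = 0
        for name, start, end in self.partitions:
            if start != pos or end <= start:
                raise ValueError(f"partition {name!r} breaks the tiling at {pos}")
            pos = end
        if self.partitions and pos != ncol:
            raise ValueError("partitions do not cover the full matrix")

    @property
    def columns(self) -> int:
        if self.partitions:
            return self.partitions[-1][2]
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def partition_lines(self) -> list[str]:
        """RAxML-style partition lines with 1-based inclusive coordinates."""
        return [f"{name} = {start + 1}-{end}" for name, start, end in self.partitions]

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{self.rows[t]}\n" for t in self.taxa)

    def to_phylip(self) -> str:
        """Relaxed PHYLIP: name, two spaces, full-row sequence."""
        pad = max(len(t) for t in self.taxa) + 2
        header = f"{self.n_taxa} {self.columns}\n"
        return header + "".join(
            f"{t:<{pad}}{self.rows[t]}\n" for t in self.taxa
        )


def concatenate(
    groups: Sequence[OrthogroupAlignment], universe: TaxonUniverse
) -> Supermatrix:
    """Column-wise concatenation of orthogroup alignments over ``universe``.

    Taxa absent from a group are filled with '-' across that group's block;
    the partition map records each group's span in concatenation order.
    """
    uni = universe.as_set()
    for g in groups:
        foreign = g.taxa - uni
        if foreign:
            raise TreeValidationError(
                f"orthogroup {g.group_id} has taxa outside the universe: "
                f"{sorted(foreign)}"
            )
    parts = []
    chunks: dict[str, list[str]] = {t: [] for t in universe.labels}
    pos = 0
    for g in groups:
        L = g.length
        parts.append((g.group_id, pos, pos + L))
        pos += L
        fill = "-" * L
        for t in universe.labels:
            chunks[t].append(g.sequences.get(t, fill))
    return Supermatrix(
        taxa=tuple(universe.labels),
        rows={t: "".join(chunks[t]) for t in universe.labels},
        partitions=tuple(parts),
    )


def _occupied_count(row: str, unoccupied: frozenset[str]) -> int:
    return len(row) - sum(row.count(c) for c in unoccupied)


def occupancy(
    matrix: Supermatrix, unoccupied_chars: frozenset[str] = DEFAULT_UNOCCUPIED
) -> float:
    """Fraction of matrix cells holding an observed residue.

    A cell counts as occupied iff its character is not in ``unoccupied_chars``
    (default: gap, '?', 'X'), so within-sequence alignment gaps count the same
    as absent-taxon fill.
    """
    total = matrix.n_taxa * matrix.columns
    if total == 0:
        return 0.0
    occ = sum(_occupied_count(matrix.rows[t], unoccupied_chars) for t in matrix.taxa)
    return occ / total


def occupancy_report(
    matrix: Supermatrix, unoccupied_chars: frozenset[str] = DEFAULT_UNOCCUPIED
) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """Overall, per-taxon and per-group occupancy breakdown."""
    per_taxon = pd.DataFrame(
        {
            "taxon": list(matrix.taxa),
            "occupied_cells": [
                _occupied_count(matrix.rows[t], unoccupied_chars) for t in matrix.taxa
            ],
            "columns": matrix.columns,
        }
    )
    per_taxon["occupancy"] = per_taxon["occupied_cells"] / per_taxon["columns"]
    group_rows = []
    for name, start, end in matrix.partitions:
        occ = sum(
            _occupied_count(matrix.rows[t][start:end], unoccupied_chars)
            for t in matrix.taxa
        )
        group_rows.append(
            {
                "group_id": name,
                "start_1based": start + 1,
                "end_1based": end,
                "occupied_cells": occ,
                "cells": (end - start) * matrix.n_taxa,
            }
        )
    per_group = pd.DataFrame(
        group_rows,
        columns=["group_id", "start_1based", "end_1based", "occupied_cells", "cells"],
    )
    if len(per_group):
        per_group["occupancy"] = per_group["occupied_cells"] / per_group["cells"]
    return occupancy(matrix, unoccupied_chars), per_taxon, per_group


def delete_taxa_matrix(matrix: Supermatrix, drop: Iterable[str]) -> Supermatrix:
    """Remove taxon rows; columns and partitions stay untouched.

    This is the matrix half of a taxon-deletion experiment: no column
    re-trimming is performed, so site coordinates remain comparable to the
    full matrix.
    """
    drop = frozenset(drop)
    unknown = drop - set(matrix.taxa)
    if unknown:
        raise TreeValidationError(f"cannot delete unknown taxa: {sorted(unknown)}")
    keep = tuple(t for t in matrix.taxa if t not in drop)
    if not keep:
        raise TreeValidationError("taxon deletion would empty the matrix")
    return Supermatrix(
        taxa=keep,
        rows={t: matrix.rows[t] for t in keep},
        partitions=matrix.partitions,
        fill_char=matrix.fill_char,
    )


def prune_gene_trees(
    genes: GeneTreeSet, drop: Iterable[str], min_leaves: int = 4
) -> GeneTreeSet:
    """Remove taxa from every gene tree; discard trees left too small.

    The gene-tree half of a taxon-deletion experiment.  Degree-2 nodes are
    suppressed after leaf removal, so every surviving tree's split set equals
    the restriction of its original splits.  Trees with fewer than
    ``min_leaves`` remaining are discarded and counted.
    """
    drop = frozenset(drop)
    kept_trees, kept_names, discarded = [], [], 0
    for tree, name in genes:
        survivors = leaf_labels(tree) - drop
        if len(survivors) < min_leaves:
            discarded += 1
            continue
        pruned = restrict_to_taxa(tree, survivors)
        kept_trees.append(pruned)
        kept_names.append(name)
    if discarded:
        logger.info(
            "prune_gene_trees: discarded %d of %d trees (< %d leaves left)",
            discarded, len(genes), min_leaves,
        )
    return GeneTreeSet(trees=kept_trees, names=kept_names, n_discarded=discarded)


# ---------------------------------------------------------------------------
# I/O


def read_orthogroup_fasta(path: str, group_id: Optional[str] = None) -> OrthogroupAlignment:
    """Read one aligned orthogroup FASTA (record ids are taxon labels)."""
    if group_id is None:
        group_id = os.path.splitext(os.path.basename(path))[0]
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate taxon {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return OrthogroupAlignment(group_id=group_id, sequences=seqs)


def read_column_scores(path: str) -> np.ndarray:
    """Read a per-column score file (whitespace/newline-separated reals)."""
    with open(path) as fh:
        return np.array([float(tok) for tok in fh.read().split()], dtype=float)


def read_orthogroup_dir(directory: str) -> list[OrthogroupAlignment]:
    """Read every ``*.fasta`` in a directory, attaching ``<stem>.scores``
    files when present.  Groups are ordered by filename."""
    groups = []
    names = sorted(
        f for f in os.listdir(directory) if f.endswith((".fasta", ".fa", ".faa"))
    )
    for fname in names:
        aln = read_orthogroup_fasta(os.path.join(directory, fname))
        score_path = os.path.join(directory, aln.group_id + ".scores")
        if os.path.exists(score_path):
            aln.column_scores = read_column_scores(score_path)
            aln.__post_init__()  # re-validate score length
        groups.append(aln)
    return groups


def write_orthogroup_fasta(aln: OrthogroupAlignment) -> str:
    return "".join(f">{t}\n{s}\n" for t, s in aln.sequences.items())


def verify_deposited_matrix(
    directory: str,
    universe: Optional[TaxonUniverse] = None,
) -> tuple[int, float]:
    """Concatenate a directory of deposited orthogroup alignments and return
    (columns, occupancy).

    Intended for checking a local copy of a study's archived per-orthogroup
    alignments against its reported supermatrix dimensions; the deposit is
    not bundled with this package.
    """
    groups = read_orthogroup_dir(directory)
    if not groups:
        raise FileNotFoundError(f"no orthogroup FASTA files found in {directory}")
    if universe is None:
        taxa = sorted(set().union(*(g.taxa for g in groups)))
        universe = TaxonUniverse.from_iterable(taxa)
    matrix = concatenate(groups, universe)
    return matrix.columns, occupancy(matrix)
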