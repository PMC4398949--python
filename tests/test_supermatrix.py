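"""ORF selection, masking, filtering, concatenation, occupancy, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloconcord import (
    GeneTreeSet,
    OrfRecord,
    OrthogroupAlignment,
    Supermatrix,
    TaxonUniverse,
    TreeValidationError,
    concatenate,
    delete_taxa_matrix,
    filter_orthogroups,
    leaf_labels,
    mask_columns,
    occupancy,
    occupancy_report,
    parse_newick,
    prune_gene_trees,
    select_longest_per_locus,
    simulate_yule_tree,
    tree_splits,
)


class TestSelectLongest:
    def test_longest_wins(self):
        recs = [OrfRecord("L1", "a", 300), OrfRecord("L1", "b", 450),
                OrfRecord("L2", "c", 120)]
        assert select_longest_per_locus(recs) == {"b", "c"}

    def test_tie_broken_by_input_order(self):
        recs = [OrfRecord("L1", "a", 300), OrfRecord("L1", "b", 300)]
        assert select_longest_per_locus(recs) == {"a"}

    def test_empty_input(self):
        assert select_longest_per_locus([]) == set()

    @settings(derandomize=True, max_examples=10)
    @given(st.integers(0, 10**6))
    def test_agrees_with_brute_force_group_by(self, seed):
        rng = np.random.default_rng(seed)
        recs = [
            OrfRecord(f"L{rng.integers(40)}", f"orf{i}", int(rng.integers(1, 1000)))
            for i in range(1000)
        ]
        # independent scan: per locus, first record attaining the max length
        expected = {}
        for rec in recs:
            best = expected.get(rec.locus_id)
            if best is None or rec.length > best.length:
                expected[rec.locus_id] = rec
        assert select_longest_per_locus(recs) == {r.orf_id for r in expected.values()}


class TestMask:
    def test_boundary_score_retained(self):
        aln = OrthogroupAlignment(
            "g", {"X": "MKLV", "Y": "MR-V"}, np.array([0.9, 0.4, 0.5, 0.2])
        )
        masked = mask_columns(aln, 0.5)
        assert masked.sequences == {"X": "ML", "Y": "M-"}
        assert list(masked.column_scores) == [0.9, 0.5]

    def test_identity_when_all_pass(self):
        aln = OrthogroupAlignment("g", {"X": "MK"}, np.array([0.9, 0.8]))
        assert mask_columns(aln, 0.5).sequences == aln.sequences

    def test_all_columns_removed_is_valid(self):
        aln = OrthogroupAlignment("g", {"X": "MK"}, np.array([0.1, 0.2]))
        masked = mask_columns(aln, 0.5)
        assert masked.length == 0
        assert filter_orthogroups([masked]) == []

    def test_missing_scores_rejected(self):
        with pytest.raises(ValueError):
            mask_columns(OrthogroupAlignment("g", {"X": "MK"}), 0.5)

    def test_score_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            OrthogroupAlignment("g", {"X": "MK"}, np.array([0.9]))


class TestFilter:
    def _group(self, n_taxa, length):
        return OrthogroupAlignment(
            f"g{n_taxa}x{length}", {f"t{i}": "A" * length for i in range(n_taxa)}
        )

    @pytest.mark.parametrize(
        "n_taxa,length,kept",
        [(4, 200, False), (5, 200, True), (10, 50, False), (10, 51, True)],
    )
    def test_exclusive_boundaries(self, n_taxa, length, kept):
        assert bool(filter_orthogroups([self._group(n_taxa, length)])) == kept

    def test_empty_list(self):
        assert filter_orthogroups([]) == []

    def test_order_preserved(self):
        groups = [self._group(6, 60), self._group(7, 70), self._group(8, 80)]
        assert [g.group_id for g in filter_orthogroups(groups)] == [
            g.group_id for g in groups
        ]


class TestConcatenate:
    def _example(self):
        g1 = OrthogroupAlignment("g1", {"X": "AAAA", "Y": "CCCC"})
        g2 = OrthogroupAlignment("g2", {"Y": "DDDDDD", "Z": "EEEEEE"})
        uni = TaxonUniverse.from_iterable(["X", "Y", "Z"])
        return concatenate([g1, g2], uni)

    def test_fill_and_dimensions(self):
        m = self._example()
        assert (m.n_taxa, m.columns) == (3, 10)
        assert m.rows["X"] == "AAAA------"
        assert m.rows["Y"] == "CCCCDDDDDD"
        assert m.rows["Z"] == "----EEEEEE"

    def test_partition_lines_one_based_inclusive(self):
        assert self._example().partition_lines() == ["g1 = 1-4", "g2 = 5-10"]

    def test_single_full_group_is_identity(self):
        g = OrthogroupAlignment("g", {"X": "MKL", "Y": "MRV"})
        m = concatenate([g], TaxonUniverse.from_iterable(["X", "Y"]))
        assert m.rows == g.sequences

    def test_foreign_taxon_rejected(self):
        g = OrthogroupAlignment("g", {"W": "MKL"})
        with pytest.raises(TreeValidationError):
            concatenate([g], TaxonUniverse.from_iterable(["X", "Y"]))

    def test_column_conservation_and_occupancy_decomposition(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(8)]
        uni = TaxonUniverse.from_iterable(taxa)
        groups = []
        for gi in range(30):
            present = [t for t in taxa if rng.random() > 0.5] or taxa[:2]
            L = int(rng.integers(5, 40))
            groups.append(OrthogroupAlignment(
                f"g{gi:02d}", {t: "K" * L for t in present}
            ))
        m = concatenate(groups, uni)
        assert m.columns == sum(g.length for g in groups)
        # per-taxon occupied cells decompose over groups (gapless sequences)
        overall, per_taxon, per_group = occupancy_report(m)
        for t in taxa:
            expected = sum(g.length for g in groups if t in g.taxa)
            got = per_taxon.loc[per_taxon["taxon"] == t, "occupied_cells"].item()
            assert got == expected
        assert overall == pytest.approx(
            per_taxon["occupied_cells"].sum() / (len(taxa) * m.columns)
        )
        assert per_group["occupied_cells"].sum() == per_taxon["occupied_cells"].sum()


class TestOccupancy:
    def test_hand_counted_example(self):
        g1 = OrthogroupAlignment("g1", {"X": "AAAA", "Y": "CCCC"})
        g2 = OrthogroupAlignment("g2", {"Y": "DDDDDD", "Z": "EEEEEE"})
        m = concatenate([g1, g2], TaxonUniverse.from_iterable(["X", "Y", "Z"]))
        assert occupancy(m) == pytest.approx(20 / 30)

    def test_extremes(self):
        full = Supermatrix(("X",), {"X": "MKLV"}, (("g", 0, 4),))
        empty = Supermatrix(("X",), {"X": "----"}, (("g", 0, 4),))
        assert occupancy(full) == 1.0
        assert occupancy(empty) == 0.0

    def test_internal_gaps_and_ambiguity_count_as_unoccupied(self):
        m = Supermatrix(("X",), {"X": "MK-X?L"}, (("g", 0, 6),))
        assert occupancy(m) == pytest.approx(3 / 6)
        assert occupancy(m, unoccupied_chars=frozenset("-")) == pytest.approx(5 / 6)

    @settings(derandomize=True, max_examples=10)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_cell_count(self, seed):
        rng = np.random.default_rng(seed)
        taxa = tuple(f"t{i}" for i in range(6))
        chars = "MKLV-?X"
        rows = {
            t: "".join(rng.choice(list(chars), size=50)) for t in taxa
        }
        m = Supermatrix(taxa, rows, (("g", 0, 50),))
        brute = sum(
            ch not in "-?X" for t in taxa for ch in rows[t]
        ) / (6 * 50)
        assert occupancy(m) == pytest.approx(brute)


class TestDeleteTaxa:
    def _matrix(self):
        taxa = tuple(f"t{i}" for i in range(10))
        rng = np.random.default_rng(3)
        rows = {t: "".join(rng.choice(list("MKLV-"), size=30)) for t in taxa}
        return Supermatrix(taxa, rows, (("g1", 0, 12), ("g2", 12, 30)))

    def test_rows_removed_columns_kept(self):
        m = self._matrix()
        out = delete_taxa_matrix(m, {"t0", "t5", "t9"})
        assert out.n_taxa == 7
        assert out.columns == m.columns
        assert out.partitions == m.partitions

    def test_empty_drop_is_identity(self):
        m = self._matrix()
        out = delete_taxa_matrix(m, set())
        assert out.rows == m.rows and out.taxa == m.taxa

    def test_unknown_taxon_rejected(self):
        with pytest.raises(TreeValidationError):
            delete_taxa_matrix(self._matrix(), {"nope"})

    def test_occupancy_consistent_with_removed_rows(self):
        m = self._matrix()
        drop = {"t1", "t2"}
        out = delete_taxa_matrix(m, drop)
        occ_all = occupancy(m) * m.n_taxa * m.columns
        occ_dropped = sum(
            ch not in "-?X" for t in drop for ch in m.rows[t]
        )
        assert occupancy(out) == pytest.approx(
            (occ_all - occ_dropped) / (out.n_taxa * out.columns)
        )


class TestPruneGeneTrees:
    def test_quartet_shrinks_below_minimum(self):
        genes = GeneTreeSet(trees=[parse_newick("((A,B),(C,D));")])
        out = prune_gene_trees(genes, {"D"})
        assert len(out) == 0 and out.n_discarded == 1

    def test_no_drop_is_identity(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        out = prune_gene_trees(GeneTreeSet(trees=[t]), set())
        assert len(out) == 1
        assert tree_splits(out.trees[0]) == tree_splits(t)

    def test_surviving_splits_equal_induced_restriction(self):
        species = simulate_yule_tree(14, 9)
        drop = frozenset(sorted(leaf_labels(species))[:4])
        keep = leaf_labels(species) - drop
        genes = GeneTreeSet(trees=[species])
        out = prune_gene_trees(genes, drop)
        induced = {s.restricted(keep) for s in tree_splits(species)} - {None}
        assert tree_splits(out.trees[0]) == induced
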