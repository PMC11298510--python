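"""The five-way join, descendant expansion, filtering and merging."""

import pytest

from tetrachord import (
    CuratedDatabase,
    NodeClass,
    QueryFilter,
    TermHierarchy,
    expand_descendants,
    filter_tetramers,
    generate_tetramers,
    merge_tetramer_sets,
    summarize,
)
from tetrachord.fixtures import (
    FixtureSpec,
    brute_force_tetramers,
    make_database,
    make_hierarchy,
    make_overlapping_pair,
    make_tetramer_table,
)
from tetrachord.model import Diagnostics


class TestFiveWayJoin:
    def test_minimal_complete_support_yields_one_tetramer(self, minimal_db):
        tset = generate_tetramers(minimal_db)
        assert len(tset) == 1
        assert tset.records[0].key == ("C1", "G1", "P1", "D1")

    def test_each_of_the_five_relations_is_necessary(self, minimal_db):
        """Removing any single supporting interaction kills the tetramer."""
        for i in range(5):
            pruned = CuratedDatabase(
                interactions=[r for j, r in enumerate(minimal_db.interactions)
                              if j != i]
            )
            assert len(generate_tetramers(pruned)) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_join_matches_brute_force_enumeration(self, seed):
        spec = FixtureSpec(n_chemicals=6, n_genes=10, n_phenotypes=10,
                           n_diseases=4, interaction_probability=0.3,
                           seed=seed)
        db, expected = make_database(spec)
        got = generate_tetramers(db)
        assert [t.key for t in got] == [t.key for t in expected]

    def test_single_deletion_removes_exactly_dependent_tetramers(self):
        """Deleting one interaction removes the tetramers it supported
        and nothing else, on every possible single deletion."""
        db, _ = make_database(FixtureSpec(
            n_chemicals=3, n_genes=4, n_phenotypes=4, n_diseases=2,
            interaction_probability=0.5, seed=11))
        full = {t.key for t in generate_tetramers(db)}
        assert full  # the check is vacuous on an empty closure
        for i, removed in enumerate(db.interactions):
            pruned = CuratedDatabase(
                interactions=db.interactions[:i] + db.interactions[i + 1:])
            remaining = {t.key for t in brute_force_tetramers(pruned)}
            got = {t.key for t in generate_tetramers(pruned)}
            assert got == remaining
            lost = full - got
            # every lost tetramer must have relied on the removed pair
            s, o = removed.subject.accession, removed.object.accession
            for key in lost:
                assert s in key and o in key

    def test_adding_interactions_is_monotone(self):
        db, _ = make_database(FixtureSpec(
            n_chemicals=4, n_genes=6, n_phenotypes=6, n_diseases=3,
            interaction_probability=0.25, seed=5))
        base = {t.key for t in generate_tetramers(db)}
        richer_db, _ = make_database(FixtureSpec(
            n_chemicals=4, n_genes=6, n_phenotypes=6, n_diseases=3,
            interaction_probability=0.25, planted=5, seed=5))
        richer = {t.key for t in generate_tetramers(richer_db)}
        assert base <= richer

    def test_output_sorted_alphabetically_by_terms(self):
        db, _ = make_database(FixtureSpec(seed=2))
        got = generate_tetramers(db)
        keys = [tuple(x for ref in t.slots
                      for x in (ref.term.casefold(), ref.accession))
                for t in got]
        assert keys == sorted(keys)

    def test_unknown_filter_accession_warns_and_matches_nothing(self,
                                                                minimal_db):
        query = QueryFilter.build(chemicals=["NOPE"])
        tset = generate_tetramers(minimal_db, query)
        assert len(tset) == 0
        assert any("NOPE" in w for w in tset.diagnostics.warnings)


class TestDescendantExpansion:
    def test_leaf_expands_to_itself(self):
        h = TermHierarchy.from_edges(NodeClass.CHEMICAL,
                                     [("metals", "copper")])
        assert expand_descendants(h, {"copper"}) == {"copper"}

    def test_metals_toy_includes_root_and_children(self):
        h = TermHierarchy.from_edges(
            NodeClass.CHEMICAL, [("metals", "copper"), ("metals", "iron")])
        assert expand_descendants(h, {"metals"}) == {"metals", "copper",
                                                     "iron"}

    def test_missing_root_returned_alone_with_note(self):
        h = TermHierarchy.from_edges(NodeClass.DISEASE, [("a", "b")])
        diag = Diagnostics()
        assert expand_descendants(h, {"zzz"}, diag) == {"zzz"}
        assert diag.warnings

    def test_random_dag_matches_path_enumeration(self):
        """Closure on a ~200-node DAG equals naive all-paths reachability."""
        h = make_hierarchy(NodeClass.PHENOTYPE, depth=4, branching=3,
                           extra_edges=60, seed=7)
        children = {}
        for parent, child in h.edges:
            children.setdefault(parent, set()).add(child)

        def reach(node, seen):
            # deliberately naive DFS enumeration as the oracle
            out = {node}
            for ch in children.get(node, ()):  # noqa: B007
                if ch not in seen:
                    out |= reach(ch, seen | {ch})
            return out

        all_nodes = sorted(h.accessions)
        assert len(all_nodes) >= 100
        for root in all_nodes[::7]:
            assert expand_descendants(h, {root}) == reach(root, {root})

    def test_hierarchy_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            TermHierarchy.from_edges(NodeClass.CHEMICAL,
                                     [("a", "b"), ("b", "a")])

    def test_generate_with_hierarchy_filter(self, minimal_db):
        """A root filter term reaches the tetramer via its descendant."""
        hier = TermHierarchy.from_edges(NodeClass.CHEMICAL,
                                        [("METALS", "C1")])
        db = CuratedDatabase(interactions=minimal_db.interactions,
                             hierarchy={NodeClass.CHEMICAL: hier})
        query = QueryFilter.build(chemicals=["METALS"],
                                  descendants=[NodeClass.CHEMICAL])
        assert len(generate_tetramers(db, query)) == 1
        # without descendant expansion the root matches nothing
        query_no_desc = QueryFilter.build(chemicals=["METALS"])
        assert len(generate_tetramers(db, query_no_desc)) == 0


class TestFilterTetramers:
    def test_empty_filter_is_identity(self):
        tset = make_tetramer_table(50, seed=1)
        out = filter_tetramers(tset, QueryFilter())
        assert [t.key for t in out] == [t.key for t in tset]

    def test_single_disease_filter_keeps_only_matches(self):
        tset = make_tetramer_table(80, cardinalities=(4, 10, 10, 3), seed=2)
        target = tset.records[0].disease.accession
        out = filter_tetramers(tset, QueryFilter.build(diseases=[target]))
        assert all(t.disease.accession == target for t in out)
        assert len(out) == sum(
            1 for t in tset if t.disease.accession == target)

    @pytest.mark.parametrize("seed", range(4))
    def test_filter_matches_row_by_row_predicate(self, seed):
        tset = make_tetramer_table(120, cardinalities=(5, 12, 12, 4),
                                   seed=seed)
        chems = {t.chemical.accession for t in tset.records[:10]}
        genes = {t.gene.accession for t in tset.records[:25]}
        query = QueryFilter.build(chemicals=chems, genes=genes)
        out = filter_tetramers(tset, query)
        expected = [t for t in tset
                    if t.chemical.accession in chems
                    and t.gene.accession in genes]
        assert [t.key for t in out] == [t.key for t in expected]

    def test_tightening_filter_never_adds_tetramers(self):
        tset = make_tetramer_table(60, cardinalities=(4, 8, 8, 3), seed=9)
        chems = sorted({t.chemical.accession for t in tset})
        loose = filter_tetramers(tset, QueryFilter.build(chemicals=chems))
        tight = filter_tetramers(tset,
                                 QueryFilter.build(chemicals=chems[:1]))
        assert {t.key for t in tight} <= {t.key for t in loose}


class TestMergeAndSummarize:
    def test_disjoint_123_122_136_concatenate_to_381(self):
        from tetrachord.fixtures import make_disjoint_tables
        sets = make_disjoint_tables([123, 122, 136], seed=0)
        merged = merge_tetramer_sets(sets)
        assert len(merged) == 381
        assert merged.unique_count() == 381

    def test_self_merge_dedup_is_idempotent(self):
        tset = make_tetramer_table(40, seed=4)
        merged = merge_tetramer_sets([tset, tset], deduplicate=True)
        assert [t.key for t in merged] == [t.key for t in tset]

    @pytest.mark.parametrize("overlap", [0, 7, 30])
    def test_planted_overlap_counting(self, overlap):
        a, b = make_overlapping_pair(60, 50, overlap, seed=overlap + 1)
        merged = merge_tetramer_sets([a, b])
        assert len(merged) == 110
        assert merged.unique_count() == 110 - overlap

    def test_merge_requires_input(self):
        with pytest.raises(ValueError):
            merge_tetramer_sets([])

    def test_concatenation_preserves_input_order(self):
        from tetrachord.fixtures import make_disjoint_tables
        a, b = make_disjoint_tables([10, 10], seed=3)
        merged = merge_tetramer_sets([a, b])
        assert [t.key for t in merged] == (
            [t.key for t in a] + [t.key for t in b])

    def test_summarize_empty_set_is_all_zero(self):
        from tetrachord import TetramerSet
        s = summarize(TetramerSet())
        assert s.to_dict() == {"records": 0, "unique_tetramers": 0,
                               "chemicals": 0, "genes": 0, "phenotypes": 0,
                               "diseases": 0}

    def test_summarize_counts_duplicates_separately(self):
        tset = make_tetramer_table(20, seed=6)
        doubled = merge_tetramer_sets([tset, tset])
        s = summarize(doubled)
        assert s.records == 40
        assert s.unique_tetramers == 20
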