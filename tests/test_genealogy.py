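"""Perfect-phylogeny reconstruction, fossil-record dating, ecotype origins."""

import pytest
from hypothesis import given, settings, strategies as st

from fossilrecord.errors import PhylogenyConflictError
from fossilrecord.genealogy import (
    MutationDate,
    build_genealogy,
    check_perfect_phylogeny,
    count_independent_origins,
    date_divergence,
    date_mutation,
    date_tree,
    dating_table,
    to_newick,
)

from conftest import clone, make_series


class TestThreeGameteTest:
    def test_nested_sets_are_compatible(self):
        clones = [clone("c1", {"A", "B"}), clone("c2", {"A"}), clone("c3", set())]
        assert check_perfect_phylogeny(clones).is_compatible

    def test_crossing_pair_conflicts(self):
        clones = [clone("c1", {"A", "B"}), clone("c2", {"A"}), clone("c3", {"B"})]
        report = check_perfect_phylogeny(clones)
        assert [(c.mutation_a, c.mutation_b) for c in report.conflicts] == [("A", "B")]
        assert report.conflicts[0].witness_both == "c1"

    def test_disjoint_clones_are_compatible(self):
        # two clones sharing no mutations: independent origins, no conflict
        clones = [clone("s1", {"A", "B"}), clone("s2", {"C", "D"})]
        assert check_perfect_phylogeny(clones).is_compatible

    def test_empty_input(self):
        assert check_perfect_phylogeny([]).is_compatible


class TestBuildGenealogy:
    def test_forced_cherry_topology(self):
        clones = [clone("c1", {"A", "B"}), clone("c2", {"A", "C"}), clone("c3", {"D"})]
        tree = build_genealogy(clones)
        # A sits on the internal edge above the (c1, c2) cherry
        internal = [
            n for n in tree.root.walk() if not n.is_leaf and n is not tree.root
        ]
        assert len(internal) == 1 and internal[0].mutations == ["A"]
        assert sorted(l.name for l in internal[0].leaves()) == ["c1", "c2"]
        assert len(tree.root.children) == 2  # cherry + c3

    def test_independent_origins_attach_at_root(self):
        clones = [
            clone("SS1", {"A", "B"}),
            clone("SS2", {"C", "D"}),
            clone("FS1", {"E", "F", "G"}, ecotype="FS"),
            clone("FS2", {"E", "F", "H"}, ecotype="FS"),
        ]
        tree = build_genealogy(clones)
        root_child_leafsets = sorted(
            tuple(sorted(l.name for l in ch.leaves())) for ch in tree.root.children
        )
        assert root_child_leafsets == [("FS1", "FS2"), ("SS1",), ("SS2",)]

    def test_single_clone_degenerate(self):
        tree = build_genealogy([clone("c1", {"A", "B"})])
        assert len(tree.root.children) == 1
        leaf = tree.root.children[0]
        assert leaf.name == "c1" and sorted(leaf.mutations) == ["A", "B"]

    def test_round_trip_reconstruction(self):
        clones = [
            clone("c1", {"A", "B", "X"}),
            clone("c2", {"A", "B", "Y"}),
            clone("c3", {"A", "Z"}),
            clone("c4", set()),
        ]
        tree = build_genealogy(clones)
        rebuilt = tree.clone_mutations()
        assert rebuilt == {c.clone_id: c.mutations for c in clones}

    def test_conflict_raises_with_report(self):
        clones = [clone("c1", {"A", "B"}), clone("c2", {"A"}), clone("c3", {"B"})]
        with pytest.raises(PhylogenyConflictError) as exc:
            build_genealogy(clones)
        assert exc.value.report.conflicting_mutations() == {"A", "B"}

    def test_greedy_fallback_drops_low_frequency_conflict(self):
        clones = [clone("c1", {"A", "B"}), clone("c2", {"A"}), clone("c3", {"B"})]
        series = make_series({"A": [0, 50, 50], "B": [0, 5, 5]}, [0, 6, 12])
        tree = build_genealogy(clones, series, drop_conflicts=True)
        assert tree.dropped_mutations == ["B"]
        assert "A" in {m for n in tree.root.walk() for m in n.mutations}

    def test_edge_mutations_ordered_by_first_detection(self):
        clones = [clone("c1", {"A", "B"}), clone("c2", {"A", "B"})]
        series = make_series({"A": [0, 0, 40], "B": [0, 30, 40]}, [0, 6, 12])
        tree = build_genealogy(clones, series)
        edge = [n for n in tree.root.walk() if n.mutations][0]
        assert edge.mutations == ["B", "A"]


class TestDating:
    DAYS = [0, 61, 72, 138, 156]  # gens 0, 408, 482, 924, 1045

    def test_midpoint_of_first_detection(self):
        s = make_series({"m": [0, 0, 10, 20, 20]}, self.DAYS)
        d = date_mutation("m", s, extraction_gen=1045)
        assert d.origin_gen == 445.0 and not d.near_end  # (408 + 482) / 2

    def test_detected_at_first_sample(self):
        s = make_series({"m": [10, 10, 10, 10, 10]}, self.DAYS)
        assert date_mutation("m", s, 1045).origin_gen == 0.0

    def test_never_detected_dated_near_extraction(self):
        s = make_series({"m": [0, 0, 0, 0, 0]}, self.DAYS)
        d = date_mutation("m", s, extraction_gen=1045)
        assert d.origin_gen == 984.5 and d.near_end  # (924 + 1045) / 2

    def test_unknown_mutation_is_lookup_error(self):
        s = make_series({"m": [0, 0, 0, 0, 0]}, self.DAYS)
        with pytest.raises(KeyError):
            date_mutation("nope", s, 1045)

    def test_divergence_midpoint(self):
        node = _node(mutations=["s1", "s2"], child_muts=[["u1"], ["u2"]])
        dates = {
            "s1": MutationDate(200),
            "s2": MutationDate(350),
            "u1": MutationDate(480),
            "u2": MutationDate(700),
        }
        gen, flag = date_divergence(node, dates)
        assert gen == 415.0 and flag is None  # (350 + 480) / 2

    def test_divergence_one_sided_at_root(self):
        node = _node(mutations=[], child_muts=[["u1"], []])
        gen, flag = date_divergence(node, {"u1": MutationDate(100)})
        assert gen == 100.0 and flag == "one-sided"

    def test_divergence_undatable(self):
        node = _node(mutations=[], child_muts=[[], []])
        gen, flag = date_divergence(node, {})
        assert gen is None and flag == "undated"

    def test_date_tree_dates_clone_only_mutations_near_end(self):
        clones = [clone("c1", {"A", "Z"}), clone("c2", {"A"})]
        s = make_series({"A": [0, 0, 10, 20, 20]}, self.DAYS)
        tree = build_genealogy(clones, s)
        date_tree(tree, s, extraction_gen=1045)
        assert tree.mutation_dates["A"].origin_gen == 445.0
        assert tree.mutation_dates["Z"].near_end
        tab = dating_table(tree)
        assert set(tab["mutation_id"]) == {"A", "Z"}
        assert tab.loc[tab.mutation_id == "Z", "flags"].item() == "near_end"

    def test_newick_has_leaves_and_comments(self):
        clones = [clone("c1", {"A", "B"}), clone("c2", {"A"})]
        s = make_series({"A": [10, 10, 10, 10, 10], "B": [0, 10, 10, 10, 10]}, self.DAYS)
        tree = build_genealogy(clones, s)
        date_tree(tree, s, 1045)
        nwk = to_newick(tree)
        assert "c1" in nwk and "c2" in nwk and "muts=" in nwk


def _node(mutations, child_muts):
    from fossilrecord.genealogy import TreeNode

    return TreeNode(
        name="n",
        mutations=mutations,
        children=[TreeNode(name=f"c{i}", mutations=m) for i, m in enumerate(child_muts)],
    )


class TestIndependentOrigins:
    def test_study_sharing_structure_gives_four(self, paper_like_ss_clones):
        assert count_independent_origins(paper_like_ss_clones, "SS") == 4

    def test_identical_clones_one_origin(self):
        clones = [clone(f"c{i}", {"A", "B"}) for i in range(5)]
        assert count_independent_origins(clones, "SS") == 1

    def test_pairwise_disjoint_clones(self):
        clones = [clone(f"c{i}", {f"m{i}"}) for i in range(7)]
        assert count_independent_origins(clones, "SS") == 7

    def test_unknown_ecotype_rejected(self):
        with pytest.raises(ValueError):
            count_independent_origins([clone("c1", {"A"})], "XX")

    def test_transitive_sharing_merges(self):
        # c1-c2 share A, c2-c3 share B: one origin via transitivity
        clones = [
            clone("c1", {"A"}),
            clone("c2", {"A", "B"}),
            clone("c3", {"B"}),
        ]
        assert count_independent_origins(clones, "SS") == 1

    @settings(derandomize=True, max_examples=40)
    @given(st.permutations(list(range(6))))
    def test_invariant_to_clone_ordering(self, order):
        base = [
            clone("18-SS1", {"a18"}, pop="p18"),
            clone("18-SS2", {"a18", "b18"}, pop="p18"),
            clone("19-SS1", {"a19"}, pop="p19"),
            clone("19-SS2", {"b19"}, pop="p19"),
            clone("20-SS1", {"a20"}, pop="p20"),
            clone("20-SS2", {"a20"}, pop="p20"),
        ]
        shuffled = [base[i] for i in order]
        assert count_independent_origins(shuffled, "SS") == 4
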