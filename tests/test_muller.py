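"""Nested lineage assignment, Muller band arithmetic, trajectory lumping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fossilrecord.genealogy import build_genealogy, date_tree
from fossilrecord.muller import (
    Lineage,
    assign_lineages,
    build_muller_table,
    lump_similar,
)

from conftest import clone, make_series

DAYS = [0, 6, 12, 19]


def _lineage(lid, parent, muts, eco="SS"):
    return Lineage(lid, parent, list(muts), eco)


class TestAssignLineages:
    def test_nested_chain_in_parent_order(self):
        # background (rbs+spoT) -> intergenic insertion -> nadR addition,
        # recovered as three nested lineages from one clone's genotype
        clones = [
            clone("SS1", {"rbs", "spoT"}),
            clone("SS2", {"rbs", "spoT", "mokB/trg"}),
            clone("SS3", {"rbs", "spoT", "mokB/trg", "nadR"}),
        ]
        series = make_series(
            {
                "rbs": [0, 40, 60, 60],
                "spoT": [0, 40, 60, 60],
                "mokB/trg": [0, 0, 20, 20],
                "nadR": [0, 0, 0, 10],
            },
            DAYS,
        )
        tree = build_genealogy(clones, series)
        date_tree(tree, series, extraction_gen=150)
        lineages = assign_lineages(tree, series)
        by_id = {l.lineage_id: l for l in lineages}
        chain = ["rbs", "mokB/trg", "nadR"]
        assert set(by_id) >= set(chain)
        assert by_id["rbs"].parent_id is None
        assert by_id["mokB/trg"].parent_id == "rbs"
        assert by_id["nadR"].parent_id == "mokB/trg"
        assert by_id["rbs"].defining_mutations == ["rbs", "spoT"]
        assert all(by_id[c].ecotype == "SS" for c in chain)

    def test_single_edge_tree(self):
        clones = [clone("c1", {"A"})]
        series = make_series({"A": [0, 10, 10, 10]}, DAYS)
        tree = build_genealogy(clones, series)
        date_tree(tree, series, 150)
        lineages = assign_lineages(tree, series)
        assert len(lineages) == 1 and lineages[0].parent_id is None

    def test_two_root_lineages(self):
        clones = [clone("c1", {"A"}), clone("c2", {"B"})]
        series = make_series({"A": [0, 10, 10, 10], "B": [0, 0, 10, 10]}, DAYS)
        tree = build_genealogy(clones, series)
        date_tree(tree, series, 150)
        lineages = assign_lineages(tree, series)
        assert {l.parent_id for l in lineages} == {None}
        assert len(lineages) == 2

    def test_undated_tree_rejected(self):
        clones = [clone("c1", {"A"})]
        series = make_series({"A": [0, 10, 10, 10]}, DAYS)
        tree = build_genealogy(clones, series)
        with pytest.raises(ValueError):
            assign_lineages(tree, series)


class TestMullerTable:
    def test_band_arithmetic(self):
        series = make_series({"P": [80] * 4, "C": [30] * 4}, DAYS)
        lineages = [_lineage("P", None, ["P"]), _lineage("C", "P", ["C"])]
        table = build_muller_table(lineages, series)
        assert np.allclose(table.bands.loc["P"], 0.5)  # parent-only band
        assert np.allclose(table.bands.loc["C"], 0.3)
        assert np.allclose(table.bands.loc["ancestral"], 0.2)
        assert table.violations == []

    def test_no_lineages_all_ancestral(self):
        series = make_series({"m": [0, 0, 0, 0]}, DAYS)
        table = build_muller_table([], series)
        assert np.allclose(table.bands.loc["ancestral"], 1.0)

    def test_child_exceeding_parent_floored_and_reported(self):
        series = make_series({"P": [50] * 4, "C": [60] * 4}, DAYS)
        lineages = [_lineage("P", None, ["P"]), _lineage("C", "P", ["C"])]
        table = build_muller_table(lineages, series, tolerance=0.05)
        assert np.allclose(table.bands.loc["C"], 0.6)
        assert np.allclose(table.bands.loc["P"], 0.0)  # floored at zero
        assert len(table.violations) == 4  # one per time point
        assert np.allclose(table.floored_mass, 0.1)  # clipped mass reported

    def test_violation_within_tolerance_not_reported(self):
        series = make_series({"P": [50] * 4, "C": [54] * 4}, DAYS)
        lineages = [_lineage("P", None, ["P"]), _lineage("C", "P", ["C"])]
        table = build_muller_table(lineages, series, tolerance=0.05)
        assert table.violations == []

    def test_conservation_with_flooring_bookkeeping(self):
        series = make_series({"P": [50] * 4, "C": [60] * 4}, DAYS)
        lineages = [_lineage("P", None, ["P"]), _lineage("C", "P", ["C"])]
        table = build_muller_table(lineages, series)
        total = table.bands.sum(axis=0) - table.floored_mass
        assert np.allclose(total, 1.0)

    def test_mean_proxy(self):
        series = make_series({"A": [40] * 4, "B": [20] * 4}, DAYS)
        lineages = [_lineage("A", None, ["A", "B"])]
        table = build_muller_table(lineages, series, proxy="mean")
        assert np.allclose(table.lineage_freq.loc["A"], 0.3)
        with pytest.raises(ValueError):
            build_muller_table(lineages, series, proxy="median")

    def test_long_format_export(self):
        series = make_series({"P": [80] * 4}, DAYS)
        lineages = [_lineage("P", None, ["P"])]
        table = build_muller_table(lineages, series)
        frame = table.to_frame(lineages, series.scale)
        assert set(frame.columns) == {
            "time_gen",
            "lineage_id",
            "parent_id",
            "band_frequency",
            "flags",
        }
        # per time point: one row per lineage plus the ancestral band
        assert len(frame) == 4 * 2


class TestLumping:
    def test_identical_trajectories_lump(self):
        series = make_series({"A": [10, 20, 30, 30], "B": [10, 20, 30, 30]}, DAYS)
        clusters = lump_similar(_lineage("A", None, ["A", "B"]), series, max_gap=0.0)
        assert len(clusters) == 1
        assert clusters[0].mutation_ids == ["A", "B"]
        assert np.allclose(clusters[0].trajectory, [0.1, 0.2, 0.3, 0.3])

    def test_zero_gap_is_identity_on_distinct_trajectories(self):
        series = make_series({"A": [10, 20, 30, 30], "B": [11, 20, 30, 30]}, DAYS)
        clusters = lump_similar(_lineage("A", None, ["A", "B"]), series, max_gap=0.0)
        assert [c.mutation_ids for c in clusters] == [["A"], ["B"]]

    def test_chaining_merges_transitively(self):
        # adjacent gaps 0.03 and 0.03, end-to-end gap 0.06 > max_gap:
        # greedy single linkage still forms one cluster of three
        series = make_series(
            {"A": [10, 10, 10, 10], "B": [13, 13, 13, 13], "C": [16, 16, 16, 16]},
            DAYS,
        )
        clusters = lump_similar(
            _lineage("A", None, ["A", "B", "C"]), series, max_gap=0.05
        )
        assert [c.mutation_ids for c in clusters] == [["A", "B", "C"]]
        assert np.allclose(clusters[0].trajectory, 0.13)

    def test_max_gap_domain(self):
        series = make_series({"A": [10, 10, 10, 10]}, DAYS)
        with pytest.raises(ValueError):
            lump_similar(_lineage("A", None, ["A"]), series, max_gap=1.5)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.lists(st.integers(0, 100), min_size=4, max_size=4),
            min_size=1,
            max_size=5,
        )
    )
    def test_lumped_mass_preserved(self, rows):
        counts = {f"m{i}": r for i, r in enumerate(rows)}
        series = make_series(counts, DAYS, totals={m: [100] * 4 for m in counts})
        lin = _lineage("m0", None, list(counts))
        clusters = lump_similar(lin, series, max_gap=0.2)
        total = sum(
            c.trajectory * len(c.mutation_ids) for c in clusters
        )
        expected = series.freq().loc[list(counts)].sum(axis=0)
        assert np.allclose(total, expected)
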