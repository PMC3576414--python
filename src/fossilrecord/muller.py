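"""Nested-lineage (Muller) frequency tables.

A Muller plot stacks lineage frequencies over time with each descendant
lineage drawn inside its parent.  Here a lineage is one edge of the clone
genealogy: the set of mutations that arose together on one genetic
background.  Mutations within a lineage are cumulative — a daughter
lineage's mutations occur on top of its parent's — so a lineage's
frequency includes all of its descendants, and the visible band width of
a lineage is its frequency minus the summed frequencies of its children.

A lineage's frequency at a time point is summarized by the frequency of
its earliest defining mutation (it tags the whole background); the
per-time-point mean of the defining mutations is available as an
alternative proxy.  Pooled-sequencing noise can make a child appear more
frequent than its parent; violations beyond a tolerance are recorded on
the output rather than raised, and band widths are floored at zero with
the clipped mass reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genealogy import GenealogyTree, TreeNode, _first_detection_gen
from .variants import FrequencySeries

ANCESTRAL_ID = "ancestral"


@dataclass
class Lineage:
    """One edge of the genealogy viewed as a Muller band."""

    lineage_id: str
    parent_id: str | None
    defining_mutations: list[str]
    ecotype: str


@dataclass
class NestingViolation:
    time_day: int
    child_id: str
    parent_id: str
    child_freq: float
    parent_freq: float


@dataclass
class MullerTable:
    """Per-time-point band widths for a nested lineage hierarchy.

    ``bands`` rows are lineage ids plus an ``ancestral`` residual row;
    columns are sample days.  ``lineage_freq`` holds the raw (cumulative)
    lineage frequencies before nesting arithmetic.  ``floored_mass`` per
    time point is the total mass clipped while flooring negative bands,
    so that band sums plus residual plus clipping account for exactly 1.
    """

    bands: pd.DataFrame
    lineage_freq: pd.DataFrame
    floored_mass: pd.Series
    violations: list[NestingViolation] = field(default_factory=list)

    def to_frame(self, lineages: Sequence[Lineage], scale) -> pd.DataFrame:
        """Long-format export: time_gen, lineage_id, parent_id, band_frequency."""
        from .variants import day_to_generation

        parent = {l.lineage_id: l.parent_id for l in lineages}
        rows = []
        for day in self.bands.columns:
            gen = day_to_generation(int(day), scale)
            for lid in self.bands.index:
                rows.append(
                    {
                        "time_gen": gen,
                        "lineage_id": lid,
                        "parent_id": parent.get(lid, "") or "",
                        "band_frequency": self.bands.at[lid, day],
                        "flags": "",
                    }
                )
        return pd.DataFrame(rows)


def assign_lineages(tree: GenealogyTree, series: FrequencySeries) -> list[Lineage]:
    """Turn every mutation-carrying edge of a dated genealogy into a lineage.

    The parent of a lineage is the nearest ancestral edge that carries
    mutations; edges without mutations (e.g. a leaf identical to its
    parent's genotype) contribute no lineage.  The ecotype tag is the
    shared ecotype of the clones below the edge, or ``other`` when mixed.
    Mutations within an edge keep their first-detection order.
    """
    if not tree.dated:
        raise ValueError("assign_lineages requires a dated tree (run date_tree)")
    ecotypes = tree.leaf_ecotypes
    lineages: list[Lineage] = []

    def leaf_names(node: TreeNode) -> list[str]:
        return [l.name for l in node.leaves()]

    def descend(node: TreeNode, parent_lineage: str | None) -> None:
        current = parent_lineage
        if node is not tree.root and node.mutations:
            lid = node.mutations[0]
            tags = {ecotypes.get(l) for l in leaf_names(node)} - {None}
            tag = tags.pop() if len(tags) == 1 else ("other" if tags else "unknown")
            lineages.append(
                Lineage(
                    lineage_id=lid,
                    parent_id=parent_lineage,
                    defining_mutations=list(node.mutations),
                    ecotype=tag,
                )
            )
            current = lid
        for child in node.children:
            descend(child, current)

    descend(tree.root, None)
    return lineages


def build_muller_table(
    lineages: Sequence[Lineage],
    series: FrequencySeries,
    tolerance: float = 0.05,
    proxy: str = "first",
) -> MullerTable:
    """Compute band widths and the ancestral residual at every time point.

    ``proxy`` selects the lineage-frequency summary: ``"first"`` (the
    earliest defining mutation, default) or ``"mean"`` (per-time-point
    mean of the defining mutations).
    """
    if proxy not in ("first", "mean"):
        raise ValueError(f"unknown lineage-frequency proxy {proxy!r}")
    freq = series.freq().fillna(0.0)
    days = series.timepoints_days
    lineage_rows = {}
    for lin in lineages:
        muts = [m for m in lin.defining_mutations if m in freq.index]
        if not muts:
            lineage_rows[lin.lineage_id] = pd.Series(0.0, index=days)
        elif proxy == "first":
            lineage_rows[lin.lineage_id] = freq.loc[muts[0]]
        else:
            lineage_rows[lin.lineage_id] = freq.loc[muts].mean(axis=0)
    lineage_freq = pd.DataFrame(lineage_rows).T.reindex(
        [l.lineage_id for l in lineages]
    )

    children: dict[str | None, list[str]] = {}
    for lin in lineages:
        children.setdefault(lin.parent_id, []).append(lin.lineage_id)

    violations: list[NestingViolation] = []
    bands = pd.DataFrame(0.0, index=list(lineage_freq.index) + [ANCESTRAL_ID], columns=days)
    floored = pd.Series(0.0, index=days)
    for lin in lineages:
        own = lineage_freq.loc[lin.lineage_id]
        kids = children.get(lin.lineage_id, [])
        kid_sum = (
            lineage_freq.loc[kids].sum(axis=0) if kids else pd.Series(0.0, index=days)
        )
        width = own - kid_sum
        for day in days:
            for kid in kids:
                cf = lineage_freq.at[kid, day]
                if cf > own[day] + tolerance:
                    violations.append(
                        NestingViolation(day, kid, lin.lineage_id, cf, own[day])
                    )
        floored += (-width).clip(lower=0.0)
        bands.loc[lin.lineage_id] = width.clip(lower=0.0)
    roots = children.get(None, [])
    root_sum = (
        lineage_freq.loc[roots].sum(axis=0) if roots else pd.Series(0.0, index=days)
    )
    residual = 1.0 - root_sum
    floored += (-residual).clip(lower=0.0)
    bands.loc[ANCESTRAL_ID] = residual.clip(lower=0.0)
    return MullerTable(bands, lineage_freq, floored, violations)


@dataclass
class MutationCluster:
    mutation_ids: list[str]
    trajectory: pd.Series


def lump_similar(
    lineage: Lineage, series: FrequencySeries, max_gap: float
) -> list[MutationCluster]:
    """Greedy single-linkage lumping of similar trajectories within a lineage.

    Walking the defining mutations in their within-edge order, a mutation
    joins the current cluster when the maximum absolute per-time-point
    frequency difference to its predecessor is at most ``max_gap``
    (chaining: members of one cluster need not all be pairwise close).
    Each cluster's displayed trajectory is the per-time-point mean of its
    members.  ``max_gap = 0`` lumps only identical trajectories.
    """
    if not 0.0 <= max_gap <= 1.0:
        raise ValueError(f"max_gap must lie in [0, 1], got {max_gap}")
    freq = series.freq().fillna(0.0)
    muts = [m for m in lineage.defining_mutations if m in freq.index]
    clusters: list[list[str]] = []
    for i, m in enumerate(muts):
        if i > 0 and (freq.loc[m] - freq.loc[muts[i - 1]]).abs().max() <= max_gap:
            clusters[-1].append(m)
        else:
            clusters.append([m])
    return [
        MutationCluster(mutation_ids=c, trajectory=freq.loc[c].mean(axis=0))
        for c in clusters
    ]
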