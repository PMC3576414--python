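"""Clone genealogies under the single-origin (perfect phylogeny) assumption.

Endpoint clones from an asexual population are related by a rooted tree in
which every mutation arose exactly once and never reverted (infinite-sites
assumption).  A binary clone x mutation matrix admits such a tree iff no
pair of mutations exhibits all three of the patterns {11, 10, 01} across
clones (the three-gamete test, rooted at the all-zeros ancestor).  When it
does, the tree is unique up to the ordering of mutations along unbranched
edges, and mutations sharing a carrier set stack on a single edge.

Mutations and divergences are dated from the pooled "fossil record":

* a mutation is dated to the midpoint between the first time point at
  which it was detected and the previous sample (or generation 0 when it
  is already present at the first sample);
* a clone-only mutation never seen in the record is dated to the midpoint
  between the last sample before clone extraction and the extraction
  generation, and flagged ``near_end``;
* a divergence is dated midway between the last mutation the clones share
  and the first mutation they do not share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .errors import PhylogenyConflictError, ValidationError
from .variants import CloneGenotype, ECOTYPES, FrequencySeries


# ---------------------------------------------------------------------------
# Compatibility checking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Conflict:
    """One pair of mutations failing the three-gamete test."""

    mutation_a: str
    mutation_b: str
    witness_both: str  # clone showing pattern 11
    witness_a_only: str  # 10
    witness_b_only: str  # 01


@dataclass
class ConflictReport:
    conflicts: list[Conflict] = field(default_factory=list)

    @property
    def is_compatible(self) -> bool:
        return not self.conflicts

    def conflicting_mutations(self) -> set[str]:
        return {m for c in self.conflicts for m in (c.mutation_a, c.mutation_b)}


def _carrier_sets(clones: Sequence[CloneGenotype]) -> dict[str, frozenset[str]]:
    carriers: dict[str, set[str]] = {}
    for c in clones:
        for m in c.mutations:
            carriers.setdefault(m, set()).add(c.clone_id)
    return {m: frozenset(s) for m, s in carriers.items()}


def check_perfect_phylogeny(clones: Sequence[CloneGenotype]) -> ConflictReport:
    """Three-gamete test on every pair of mutation columns.

    Two mutations conflict when some clone carries both, another carries
    only the first, and a third carries only the second; with the
    all-zeros ancestor as root this is exactly incompatibility with a
    perfect phylogeny.
    """
    carriers = _carrier_sets(clones)
    muts = sorted(carriers)
    report = ConflictReport()
    for i, a in enumerate(muts):
        sa = carriers[a]
        for b in muts[i + 1 :]:
            sb = carriers[b]
            both = sa & sb
            a_only = sa - sb
            b_only = sb - sa
            if both and a_only and b_only:
                report.conflicts.append(
                    Conflict(a, b, min(both), min(a_only), min(b_only))
                )
    return report


# ---------------------------------------------------------------------------
# Tree structure and construction
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a clone genealogy; ``mutations`` sit on the edge above it."""

    name: str
    mutations: list[str] = field(default_factory=list)
    children: list["TreeNode"] = field(default_factory=list)
    divergence_gen: float | None = None
    divergence_flag: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]


@dataclass
class MutationDate:
    origin_gen: float
    near_end: bool = False


@dataclass
class GenealogyTree:
    population_id: str
    root: TreeNode
    mutation_dates: dict[str, MutationDate] = field(default_factory=dict)
    leaf_ecotypes: dict[str, str] = field(default_factory=dict)
    dropped_mutations: list[str] = field(default_factory=list)
    dated: bool = False

    def clone_mutations(self) -> dict[str, frozenset[str]]:
        """Reconstruct each clone's mutation set from its root-to-leaf path."""
        out: dict[str, frozenset[str]] = {}

        def descend(node: TreeNode, acc: tuple[str, ...]) -> None:
            acc = acc + tuple(node.mutations)
            if node.is_leaf and node is not self.root:
                out[node.name] = frozenset(acc)
            for child in node.children:
                descend(child, acc)

        descend(self.root, ())
        return out

    def edges(self) -> list[TreeNode]:
        """Non-root nodes, i.e. one per edge."""
        return [n for n in self.root.walk() if n is not self.root]


def build_genealogy(
    clones: Sequence[CloneGenotype],
    series: FrequencySeries | None = None,
    drop_conflicts: bool = False,
) -> GenealogyTree:
    """Construct the perfect phylogeny of a set of clones.

    Mutations with identical carrier sets share an edge; carrier sets form
    a laminar family (guaranteed by compatibility), so containment defines
    the topology.  Clones sharing no mutation with anything attach
    directly to the ancestral root.  Mutations along one edge are ordered
    by first detection in ``series`` when given (ties broken by descending
    mean frequency, then mutation id).

    On a three-gamete conflict the default is to fail with
    :class:`PhylogenyConflictError`; ``drop_conflicts=True`` instead
    iteratively removes, from each conflicting pair, the mutation with the
    lower maximum observed frequency (pooled linkage miscalls are usually
    rare variants) and retries.
    """
    if not clones:
        raise ValueError("need at least one clone")
    populations = {c.population_id for c in clones}
    if len(populations) > 1:
        raise ValidationError(f"clones span multiple populations: {populations}")

    report = check_perfect_phylogeny(clones)
    dropped: list[str] = []
    if not report.is_compatible:
        if not drop_conflicts:
            raise PhylogenyConflictError(report)
        clones, dropped = _drop_conflicting(clones, report, series)

    carriers = _carrier_sets(clones)
    by_set: dict[frozenset[str], list[str]] = {}
    for m, s in carriers.items():
        by_set.setdefault(s, []).append(m)

    root = TreeNode(name=f"{populations.pop()}_ancestor")
    nodes: dict[frozenset[str], TreeNode] = {}
    internal_sets = sorted(
        (s for s in by_set if len(s) >= 2), key=lambda s: (-len(s), sorted(s))
    )
    for idx, s in enumerate(internal_sets):
        nodes[s] = TreeNode(name=f"n{idx}")
    # parent of a carrier set = smallest strictly containing set, else root
    for s in internal_sets:
        parent = _smallest_superset(s, internal_sets)
        (nodes[parent] if parent else root).children.append(nodes[s])
    for c in sorted(clones, key=lambda c: c.clone_id):
        leaf = TreeNode(name=c.clone_id)
        own = by_set.get(frozenset({c.clone_id}), [])
        leaf.mutations = list(own)
        host = _smallest_superset(frozenset({c.clone_id}), internal_sets)
        (nodes[host] if host else root).children.append(leaf)
    for s, node in nodes.items():
        node.mutations = list(by_set[s])

    tree = GenealogyTree(
        population_id=clones[0].population_id,
        root=root,
        leaf_ecotypes={c.clone_id: c.ecotype for c in clones},
        dropped_mutations=dropped,
    )
    for node in root.walk():
        node.mutations = _order_edge_mutations(node.mutations, series)
    return tree


def _smallest_superset(
    s: frozenset[str], candidates: Sequence[frozenset[str]]
) -> frozenset[str] | None:
    best = None
    for t in candidates:
        if s < t and (best is None or len(t) < len(best)):
            best = t
    return best


def _drop_conflicting(
    clones: Sequence[CloneGenotype],
    report: ConflictReport,
    series: FrequencySeries | None,
) -> tuple[list[CloneGenotype], list[str]]:
    max_freq: Mapping[str, float] = {}
    if series is not None:
        max_freq = series.freq().max(axis=1).fillna(0.0).to_dict()
    dropped: list[str] = []
    current = list(clones)
    while True:
        rep = check_perfect_phylogeny(current)
        if rep.is_compatible:
            return current, dropped
        candidates = sorted(
            rep.conflicting_mutations(), key=lambda m: (max_freq.get(m, 0.0), m)
        )
        victim = candidates[0]
        dropped.append(victim)
        current = [
            CloneGenotype(
                c.clone_id,
                c.population_id,
                c.ecotype,
                c.mutations - {victim},
                c.extraction_day,
            )
            for c in current
        ]


def _first_detection_gen(series: FrequencySeries) -> dict[str, float]:
    det = series.detected()
    gens = series.timepoints_gen
    out = {}
    for mid in series.mutation_ids:
        row = det.loc[mid]
        hits = [gens[j] for j in range(len(gens)) if row.iloc[j]]
        if hits:
            out[mid] = float(hits[0])
    return out


def _order_edge_mutations(
    mutations: list[str], series: FrequencySeries | None
) -> list[str]:
    if series is None:
        return sorted(mutations)
    first = _first_detection_gen(series)
    mean_freq = series.freq().mean(axis=1).fillna(0.0).to_dict()
    return sorted(
        mutations,
        key=lambda m: (first.get(m, float("inf")), -mean_freq.get(m, 0.0), m),
    )


# ---------------------------------------------------------------------------
# Dating
# ---------------------------------------------------------------------------


def date_mutation(
    mutation_id: str,
    series: FrequencySeries,
    extraction_gen: int,
) -> MutationDate:
    """Date one mutation from its first detection in the fossil record."""
    if mutation_id not in series.alt.index:
        raise KeyError(f"unknown mutation id {mutation_id!r}")
    det = series.detected().loc[mutation_id]
    gens = series.timepoints_gen
    for j, hit in enumerate(det):
        if hit:
            prev = gens[j - 1] if j > 0 else 0
            return MutationDate(origin_gen=(gens[j] + prev) / 2.0)
    return _near_end_date(series, extraction_gen)


def _near_end_date(series: FrequencySeries, extraction_gen: int) -> MutationDate:
    before = [g for g in series.timepoints_gen if g < extraction_gen]
    prev = before[-1] if before else 0
    return MutationDate(origin_gen=(extraction_gen + prev) / 2.0, near_end=True)


def date_divergence(
    node: TreeNode, dates: Mapping[str, MutationDate]
) -> tuple[float | None, str | None]:
    """Date the divergence at an internal node.

    Midpoint between the last mutation the descendants share (the parent
    edge, i.e. ``node.mutations``) and the first mutation they do not
    share (the earliest mutation on any child edge).  With one side empty
    the boundary of the other side is returned, flagged ``one-sided``;
    with both empty the divergence is undatable.
    """
    shared = [dates[m].origin_gen for m in node.mutations if m in dates]
    below = [
        dates[m].origin_gen
        for child in node.children
        for m in child.mutations
        if m in dates
    ]
    if shared and below:
        return (max(shared) + min(below)) / 2.0, None
    if below:
        return min(below), "one-sided"
    if shared:
        return max(shared), "one-sided"
    return None, "undated"


def date_tree(
    tree: GenealogyTree,
    series: FrequencySeries,
    extraction_gen: int,
) -> GenealogyTree:
    """Date every mutation and every internal divergence of a genealogy.

    Mutations absent from the series entirely (clone-only, never assayed)
    are dated near-end relative to ``extraction_gen``.
    """
    for node in tree.root.walk():
        for m in node.mutations:
            if m in series.alt.index:
                tree.mutation_dates[m] = date_mutation(m, series, extraction_gen)
            else:
                tree.mutation_dates[m] = _near_end_date(series, extraction_gen)
    for node in tree.root.walk():
        if not node.is_leaf and node is not tree.root:
            node.divergence_gen, node.divergence_flag = date_divergence(
                node, tree.mutation_dates
            )
    tree.dated = True
    return tree


# ---------------------------------------------------------------------------
# Independent ecotype origins
# ---------------------------------------------------------------------------


def ecotype_origin_groups(
    clones: Sequence[CloneGenotype], ecotype: str
) -> dict[str, list[list[CloneGenotype]]]:
    """Group same-ecotype clones, per population, by shared ancestry.

    Within a population, two clones of the ecotype belong to the same
    origin when they are connected through the transitive closure of
    "shares at least one mutation".  Origins never merge across
    populations.
    """
    if ecotype not in ECOTYPES:
        raise ValueError(f"unknown ecotype {ecotype!r}")
    by_pop: dict[str, list[CloneGenotype]] = {}
    for c in clones:
        if c.ecotype == ecotype:
            by_pop.setdefault(c.population_id, []).append(c)
    groups: dict[str, list[list[CloneGenotype]]] = {}
    for pop, members in sorted(by_pop.items()):
        members = sorted(members, key=lambda c: c.clone_id)
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[i].mutations & members[j].mutations:
                    parent[find(i)] = find(j)
        comps: dict[int, list[CloneGenotype]] = {}
        for i, c in enumerate(members):
            comps.setdefault(find(i), []).append(c)
        groups[pop] = list(comps.values())
    return groups


def count_independent_origins(clones: Sequence[CloneGenotype], ecotype: str) -> int:
    """Number of independent origins of an ecotype across all populations."""
    return sum(len(g) for g in ecotype_origin_groups(clones, ecotype).values())


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def to_newick(tree: GenealogyTree) -> str:
    """Serialize a genealogy as Newick with edge comments.

    Each edge comment lists its mutations with origin generations; branch
    lengths are generations between parent and child divergence dates when
    the tree is dated.
    """
    dtree = dendropy.Tree()
    dtree.seed_node.label = tree.root.name

    def node_age(n: TreeNode, default: float) -> float:
        return n.divergence_gen if n.divergence_gen is not None else default

    def attach(src: TreeNode, dst: dendropy.Node, parent_age: float) -> None:
        for child in src.children:
            dnode = dendropy.Node(label=child.name)
            if child.is_leaf:
                dnode.taxon = dtree.taxon_namespace.new_taxon(label=child.name)
            dst.add_child(dnode)
            if tree.dated:
                age = node_age(child, parent_age)
                dnode.edge.length = max(0.0, age - parent_age)
            if child.mutations:
                parts = []
                for m in child.mutations:
                    d = tree.mutation_dates.get(m)
                    parts.append(f"{m}@{d.origin_gen:g}" if d else m)
                dnode.comments.append("muts=" + "|".join(parts))
            attach(child, dnode, node_age(child, parent_age))
        return

    root_age = 0.0
    attach(tree.root, dtree.seed_node, root_age)
    return dtree.as_string(
        schema="newick", suppress_rooting=True, suppress_item_comments=False
    ).strip()


def dating_table(tree: GenealogyTree) -> pd.DataFrame:
    """Companion table: mutation, carrying edge, origin generation, flags."""
    rows = []
    for node in tree.root.walk():
        for m in node.mutations:
            d = tree.mutation_dates.get(m)
            rows.append(
                {
                    "mutation_id": m,
                    "edge": node.name,
                    "origin_gen": d.origin_gen if d else float("nan"),
                    "flags": "near_end" if d and d.near_end else "",
                }
            )
    return pd.DataFrame(rows, columns=["mutation_id", "edge", "origin_gen", "flags"])
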