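"""Cross-population genetic parallelism and the FS-vs-SS mutation-count test.

Replicate populations evolving the same pair of ecotypes can converge at
three genetic resolutions: the identical nucleotide change, a different
change in the same codon, or a different change in the same gene (for
intergenic mutations, the same intergenic region).  For every mutation we
report the finest level at which another population carries a
same-ecotype mutation at the matching locus.

The FS-vs-SS comparison is a paired t-test on mean per-clone mutation
counts, pairing FS against SS within a population and counting each
genealogically independent ecotype origin as its own comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genealogy import ecotype_origin_groups
from .variants import CloneGenotype, MutationRecord

MATCH_LEVELS = ("nucleotide", "codon", "gene", "none")


@dataclass
class ParallelismSummary:
    """Finest cross-population match level per mutation, plus totals."""

    match_level: dict[str, str]
    counts: dict[str, int]
    n_total: int

    @property
    def fraction_matched(self) -> float:
        """Fraction of mutations matched at any level."""
        if self.n_total == 0:
            return 0.0
        return 1.0 - self.counts["none"] / self.n_total


def ecotype_associations(
    records: Sequence[MutationRecord], clones: Sequence[CloneGenotype]
) -> dict[str, str]:
    """Associate each mutation with an ecotype via the clones carrying it.

    A mutation carried only by FS clones is FS-associated, only by SS
    clones SS-associated; carried by both (or by none) it gets no
    association and is excluded from parallelism scoring.
    """
    assoc: dict[str, set[str]] = {}
    for c in clones:
        for m in c.mutations:
            assoc.setdefault(m, set()).add(c.ecotype)
    return {
        m: ecos.pop()
        for m, ecos in assoc.items()
        if len(ecos) == 1 and next(iter(ecos)) in ("FS", "SS")
    }


def _match_level(
    rec: MutationRecord, others: Sequence[MutationRecord]
) -> str:
    level = "none"
    for o in others:
        if (
            o.position == rec.position
            and o.ref_allele == rec.ref_allele
            and o.alt_allele == rec.alt_allele
            and o.mclass == rec.mclass
        ):
            return "nucleotide"
        if (
            rec.codon is not None
            and o.codon == rec.codon
            and o.gene == rec.gene
        ):
            level = "codon" if level == "none" or level == "gene" else level
        elif o.gene == rec.gene and level == "none":
            level = "gene"
    return level


def parallelism_levels(
    records: Sequence[MutationRecord],
    associations: Mapping[str, str],
) -> ParallelismSummary:
    """Score every ecotype-associated mutation against the other populations.

    ``associations`` maps mutation_id to its ecotype (FS or SS); mutations
    without an association are ignored.  Requires mutations from at least
    two populations.
    """
    scored = [r for r in records if r.mutation_id in associations]
    populations = {r.population_id for r in scored}
    if len(populations) < 2:
        raise ValueError("parallelism requires mutations from >= 2 populations")
    match_level: dict[str, str] = {}
    for rec in scored:
        eco = associations[rec.mutation_id]
        others = [
            o
            for o in scored
            if o.population_id != rec.population_id
            and associations[o.mutation_id] == eco
        ]
        match_level[rec.mutation_id] = _match_level(rec, others)
    counts = {lvl: 0 for lvl in MATCH_LEVELS}
    for lvl in match_level.values():
        counts[lvl] += 1
    return ParallelismSummary(match_level, counts, n_total=len(scored))


@dataclass
class PairedComparison:
    pairs: list[tuple[float, float]]
    t_statistic: float
    degrees_of_freedom: int
    two_tailed_p: float
    zero_variance: bool = False


def paired_t_test(pairs: Sequence[tuple[float, float]]) -> PairedComparison:
    """Paired t-test on (first, second) count pairs; two-tailed p.

    Zero variance of the differences with a nonzero mean makes t infinite;
    the result is then reported with p = 0 and flagged.
    """
    if len(pairs) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    diffs = a - b
    df = len(pairs) - 1
    if np.allclose(np.std(diffs, ddof=1), 0.0):
        if np.allclose(diffs.mean(), 0.0):
            return PairedComparison(list(pairs), 0.0, df, 1.0)
        t = float("inf") if diffs.mean() > 0 else float("-inf")
        return PairedComparison(list(pairs), t, df, 0.0, zero_variance=True)
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(list(pairs), float(t), df, float(p))


def independent_fs_ss_pairs(
    clones: Sequence[CloneGenotype],
) -> list[tuple[float, float]]:
    """Build genealogically independent (FS, SS) mutation-count pairs.

    Within each population, clones of each ecotype are grouped into
    independent origins (transitive sharing of mutations); every FS-origin
    x SS-origin combination within a population contributes one pair of
    mean per-clone mutation counts.  A population with one FS and one SS
    origin thus yields one comparison; two independent SS origins yield
    two.
    """
    fs_groups = ecotype_origin_groups(clones, "FS")
    ss_groups = ecotype_origin_groups(clones, "SS")
    pairs: list[tuple[float, float]] = []
    for pop in sorted(set(fs_groups) | set(ss_groups)):
        for fg in fs_groups.get(pop, []):
            for sg in ss_groups.get(pop, []):
                fs_mean = float(np.mean([len(c.mutations) for c in fg]))
                ss_mean = float(np.mean([len(c.mutations) for c in sg]))
                pairs.append((fs_mean, ss_mean))
    return pairs
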