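"""Wright-Fisher simulator of an evolve-and-resequence experiment.

Generates synthetic "fossil records" with full ground truth: a well-mixed
asexual population of constant effective size Ne evolves by discrete
Wright-Fisher generations under mutation, selection and drift; whole-
population samples are taken at configured days with binomial sequencing
noise at configurable coverage, and clones are drawn at an extraction day.

Model
-----
Genotypes are whole genomes (no recombination); each new mutation is
unique (infinite sites), so true clone matrices always admit a perfect
phylogeny.  Each generation the next population is multinomial with
expected proportions x_g * w_g / sum(x * w), where the fitness of
genotype g is

    w_g = 1 + sum_i s_i  [+ a_E - b_E * x_E  with the ecotype model on]

with s_i the selection coefficients of g's mutations and x_E the current
total frequency of g's ecotype E.  The ecotype term is the simplest
negative frequency-dependent fitness: a rare ecotype with a positive base
advantage a_E invades, and the penalty b_E * x_E caps its rise, allowing
stable coexistence — the qualitative signature of niche construction.
With the ecotype model off and unequal selection coefficients, dynamics
are ordinary clonal-interference sweeps ending in fixation.

New beneficial mutations arise Poisson(mu * Ne) per generation, each on a
parent genotype drawn by frequency, with s from a configurable
distribution; a mutation switches its carrier's ecotype with a
configurable probability (how diversification enters the model).

All randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variants import (
    CloneGenotype,
    FrequencySeries,
    GenerationScale,
    MutationRecord,
    day_to_generation,
)

#: The archived sampling schedule emulated by default (days).
DEFAULT_SAMPLING_DAYS = (0, 6, 12, 19, 30, 40, 51, 61, 72, 82, 96, 111, 124, 138, 156, 183)

#: Denominator used for noise-free ("infinite coverage") records.  A power
#: of two keeps alt/total bit-exact equal to the true frequency, and any
#: nonzero frequency maps to alt >> 1 so detection and single-read masking
#: behave as for real counts.
EXACT_COVERAGE_DENOM = 2**30


@dataclass(frozen=True)
class EcotypeParams:
    """Negative frequency-dependent fitness term a - b * x for one ecotype."""

    base_advantage: float
    frequency_penalty: float


@dataclass(frozen=True)
class StandingVariant:
    """A variant present at time zero (initial polymorphism)."""

    frequency: float
    s: float = 0.0
    ecotype: str = "ancestral"


@dataclass(frozen=True)
class SimConfig:
    ne: int = 10_000
    n_generations: int = 1230
    mu: float = 0.0
    s_dist: tuple[str, float] = ("exponential", 0.02)
    ecotype_model: dict[str, EcotypeParams] | None = None
    ecotype_switch_prob: float = 0.0
    standing_variants: tuple[StandingVariant, ...] = ()
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    gens_per_day: float = 6.7
    coverage: int | Sequence[int] | None = 100
    n_clones: int = 4
    clone_day: int = 156
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ne <= 0 or self.n_generations <= 0:
            raise ValueError("ne and n_generations must be positive")
        if self.mu < 0 or self.ecotype_switch_prob < 0:
            raise ValueError("rates must be non-negative")
        max_day = self.n_generations / self.gens_per_day
        if any(d < 0 or d > max_day for d in self.sampling_days):
            raise ValueError("sampling_days must lie within the simulated range")
        for sv in self.standing_variants:
            if not 0.0 <= sv.frequency <= 1.0:
                raise ValueError("standing variant frequency must lie in [0, 1]")

    @property
    def scale(self) -> GenerationScale:
        return GenerationScale(self.gens_per_day)


@dataclass
class Genotype:
    genotype_id: int
    parent_id: int | None
    mutations: tuple[str, ...]
    ecotype: str
    fitness_sum: float  # 1 + sum of selection coefficients
    origin_gen: int


@dataclass
class SimTruth:
    """Complete ground truth of one simulation run."""

    config: SimConfig
    genotypes: dict[int, Genotype]
    #: per recorded generation: {genotype_id: frequency}
    freqs: dict[int, dict[int, float]]
    mutation_origin: dict[str, int]
    mutation_s: dict[str, float]

    def mutation_frequency(self, mutation_id: str, gen: int) -> float:
        """True population frequency of a mutation at a recorded generation."""
        return sum(
            f
            for gid, f in self.freqs[gen].items()
            if mutation_id in self.genotypes[gid].mutations
        )

    def ecotype_frequency(self, ecotype: str, gen: int) -> float:
        return sum(
            f
            for gid, f in self.freqs[gen].items()
            if self.genotypes[gid].ecotype == ecotype
        )

    def surviving_ecotypes(self, gen: int | None = None) -> set[str]:
        gen = self.config.n_generations if gen is None else gen
        return {
            self.genotypes[gid].ecotype
            for gid, f in self.freqs[gen].items()
            if f > 0
        }

    def all_mutations(self) -> list[str]:
        return sorted(self.mutation_origin)


def _draw_s(rng: np.random.Generator, s_dist: tuple[str, float]) -> float:
    family, param = s_dist
    if family == "exponential":
        return float(rng.exponential(param))
    if family == "constant":
        return float(param)
    raise ValueError(f"unknown selection-coefficient family {family!r}")


def simulate(config: SimConfig) -> SimTruth:
    """Run one Wright-Fisher simulation, recording every generation."""
    rng = np.random.default_rng(config.seed)
    ne = config.ne

    genotypes: dict[int, Genotype] = {
        0: Genotype(0, None, (), "ancestral", 1.0, 0)
    }
    counts: dict[int, int] = {0: ne}
    mutation_origin: dict[str, int] = {}
    mutation_s: dict[str, float] = {}
    next_gid = 1
    # seed initial polymorphism
    for k, sv in enumerate(config.standing_variants):
        n = int(round(sv.frequency * ne))
        n = min(n, counts.get(0, 0))
        if n <= 0:
            continue
        mid = f"sv{k}"
        g = Genotype(next_gid, 0, (mid,), sv.ecotype, 1.0 + sv.s, 0)
        genotypes[next_gid] = g
        counts[next_gid] = n
        counts[0] -= n
        mutation_origin[mid] = 0
        mutation_s[mid] = sv.s
        next_gid += 1
    if counts.get(0) == 0:
        del counts[0]

    freqs: dict[int, dict[int, float]] = {
        0: {gid: c / ne for gid, c in counts.items()}
    }

    eco_model = config.ecotype_model
    for gen in range(1, config.n_generations + 1):
        gids = sorted(counts)
        x = np.array([counts[g] / ne for g in gids])
        w = np.array([genotypes[g].fitness_sum for g in gids])
        if eco_model:
            eco_freq: dict[str, float] = {}
            for gid, xi in zip(gids, x):
                eco = genotypes[gid].ecotype
                eco_freq[eco] = eco_freq.get(eco, 0.0) + xi
            for i, gid in enumerate(gids):
                params = eco_model.get(genotypes[gid].ecotype)
                if params is not None:
                    w[i] += (
                        params.base_advantage
                        - params.frequency_penalty * eco_freq[genotypes[gid].ecotype]
                    )
        w = np.maximum(w, 1e-9)
        probs = x * w
        probs /= probs.sum()
        new_counts = rng.multinomial(ne, probs)
        counts = {g: int(c) for g, c in zip(gids, new_counts) if c > 0}

        if config.mu > 0:
            n_new = rng.poisson(config.mu * ne)
            for _ in range(n_new):
                if not counts:
                    break
                gids = sorted(counts)
                weights = np.array([counts[g] for g in gids], dtype=float)
                parent = int(rng.choice(gids, p=weights / weights.sum()))
                mid = f"m{len(mutation_origin)}"
                s = _draw_s(rng, config.s_dist)
                eco = genotypes[parent].ecotype
                if config.ecotype_switch_prob > 0 and rng.random() < config.ecotype_switch_prob:
                    eco = rng.choice([e for e in ("FS", "SS") if e != eco] or ["FS"])
                g = Genotype(
                    next_gid,
                    parent,
                    genotypes[parent].mutations + (mid,),
                    str(eco),
                    genotypes[parent].fitness_sum + s,
                    gen,
                )
                genotypes[next_gid] = g
                counts[parent] -= 1
                if counts[parent] == 0:
                    del counts[parent]
                counts[next_gid] = 1
                mutation_origin[mid] = gen
                mutation_s[mid] = s
                next_gid += 1

        freqs[gen] = {gid: c / ne for gid, c in counts.items()}

    return SimTruth(config, genotypes, freqs, mutation_origin, mutation_s)


def sample_fossil_record(
    truth: SimTruth,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> FrequencySeries:
    """Sequence the simulated population at the configured sampling days.

    At each sampled day (converted to generations), every mutation's
    alt-read count is Binomial(coverage, true frequency) with total reads
    equal to the coverage; ``coverage=None`` (infinite) records the exact
    frequencies over the power-of-two denominator ``EXACT_COVERAGE_DENOM``.
    """
    config = config or truth.config
    rng = rng or np.random.default_rng(config.seed + 1)
    days = list(config.sampling_days)
    coverages = _per_day_coverage(config.coverage, len(days))
    muts = truth.all_mutations()
    alt = np.zeros((len(muts), len(days)))
    total = np.zeros((len(muts), len(days)))
    for j, (day, cov) in enumerate(zip(days, coverages)):
        gen = min(day_to_generation(day, config.scale), config.n_generations)
        for i, m in enumerate(muts):
            # summing many c/Ne terms can overshoot [0, 1] by an ulp
            f = min(1.0, max(0.0, truth.mutation_frequency(m, gen)))
            if cov is None:
                alt[i, j] = f * EXACT_COVERAGE_DENOM
                total[i, j] = EXACT_COVERAGE_DENOM
            else:
                alt[i, j] = rng.binomial(cov, f)
                total[i, j] = cov
    return FrequencySeries(
        "sim",
        pd.DataFrame(alt, index=muts, columns=days),
        pd.DataFrame(total, index=muts, columns=days),
        config.scale,
    )


def _per_day_coverage(coverage, n_days: int) -> list[int | None]:
    if coverage is None or isinstance(coverage, (int, np.integer)):
        return [coverage] * n_days
    coverage = list(coverage)
    if len(coverage) != n_days:
        raise ValueError("per-day coverage list must match sampling_days")
    return coverage


def sample_clones(
    truth: SimTruth,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[CloneGenotype]:
    """Draw endpoint clones by genotype frequency at the extraction day."""
    config = config or truth.config
    rng = rng or np.random.default_rng(config.seed + 2)
    gen = min(day_to_generation(config.clone_day, config.scale), config.n_generations)
    pool = truth.freqs[gen]
    gids = sorted(pool)
    if not gids or config.n_clones == 0:
        return []
    probs = np.array([pool[g] for g in gids])
    probs /= probs.sum()
    draws = rng.choice(gids, size=config.n_clones, p=probs)
    return [
        CloneGenotype(
            clone_id=f"clone{k}",
            population_id="sim",
            ecotype=_map_ecotype(truth.genotypes[int(g)].ecotype),
            mutations=frozenset(truth.genotypes[int(g)].mutations),
            extraction_day=config.clone_day,
        )
        for k, g in enumerate(draws)
    ]


def _map_ecotype(eco: str) -> str:
    return eco if eco in ("FS", "SS", "ancestral") else "unknown"


def mutation_records(truth: SimTruth) -> list[MutationRecord]:
    """Synthesize annotation records for the simulated mutations.

    Positions are assigned deterministically from the mutation index;
    genes/codons are synthetic labels so downstream table I/O and
    parallelism plumbing can run on simulated data.
    """
    recs = []
    for i, m in enumerate(truth.all_mutations()):
        recs.append(
            MutationRecord(
                mutation_id=m,
                population_id="sim",
                position=1000 + 17 * i,
                ref_allele="A",
                alt_allele="G",
                mclass="SNP",
                gene=f"gene{i % 37}",
                codon=1 + (i % 211),
                synonymous=False,
            )
        )
    return recs


# ---------------------------------------------------------------------------
# Fast single-locus helpers (calibration workhorses)
# ---------------------------------------------------------------------------


def neutral_allele_trajectories(
    ne: int,
    p0: float,
    n_generations: int,
    n_replicates: int,
    rng: np.random.Generator,
    record_every: int = 1,
) -> np.ndarray:
    """Vectorized neutral Wright-Fisher allele trajectories.

    Each replicate follows p(t+1) ~ Binomial(Ne, p(t)) / Ne, the same law
    as :func:`simulate` with mu = 0 and a single neutral standing variant.
    Returns an array of shape (n_recorded + 1, n_replicates) including the
    initial frequency.
    """
    p = np.full(n_replicates, p0)
    out = [p.copy()]
    for gen in range(1, n_generations + 1):
        p = rng.binomial(ne, p) / ne
        if gen % record_every == 0:
            out.append(p.copy())
    return np.asarray(out)


def replicator_ecotype_freqs(
    model: dict[str, EcotypeParams],
    x0: dict[str, float],
    n_steps: int,
) -> dict[str, float]:
    """Deterministic (infinite-Ne, drift-free) ecotype dynamics.

    Iterates x_E <- x_E * w_E / wbar with w_E = 1 + a_E - b_E * x_E; the
    fixed point of the two-ecotype case balances the frequency-dependent
    fitnesses of the two types.
    """
    ecos = sorted(x0)
    x = np.array([x0[e] for e in ecos], dtype=float)
    x /= x.sum()
    for _ in range(n_steps):
        w = np.array(
            [
                1.0 + model[e].base_advantage - model[e].frequency_penalty * xi
                for e, xi in zip(ecos, x)
            ]
        )
        x = x * w / (x * w).sum()
    return dict(zip(ecos, x))
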