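"""Core data types for pooled-sequencing variant time series.

An evolve-and-resequence experiment archives whole-population samples at
intervals (the "fossil record").  Pooled sequencing of each archived sample
yields, for every mutation, an alternate-read count and a total-read count
per time point; endpoint clones provide phased genotypes.  This module
houses those containers, the TSV dialects used to exchange them, the
variant-reporting filters, and the day-to-generation conversion used
throughout the package.

Reporting filters
-----------------
A mutation is reported when it is detected in at least two time-point
samples of the same population AND reaches at least 5% frequency in one of
them, OR when it is carried by a sequenced clone (clone-backed mutations
are reported regardless of their pooled frequency).  Observations supported
by a single read are treated as undetected unless the next time point shows
multiple supporting reads; this masking is applied before the
two-sample/5% evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MUTATION_CLASSES = frozenset(
    {"SNP", "insertion", "deletion", "IS_insertion", "large_deletion"}
)

ECOTYPES = frozenset({"FS", "SS", "ancestral", "unknown"})

#: Fixed metadata columns of the variant-table TSV, in order.
VARIANT_META_COLUMNS = [
    "population",
    "mutation_id",
    "position",
    "ref",
    "alt",
    "class",
    "gene",
    "codon",
    "synonymous",
]

CLONE_COLUMNS = ["clone_id", "population", "ecotype", "extraction_day", "mutations"]


@dataclass(frozen=True)
class GenerationScale:
    """Conversion between experiment days and bacterial generations.

    Serial-transfer batch culture gives roughly log2(dilution factor)
    generations per day; the default 6.7 generations/day corresponds to a
    daily 1:100 transfer regime.
    """

    gens_per_day: float = 6.7

    def __post_init__(self) -> None:
        if self.gens_per_day <= 0:
            raise ValueError("gens_per_day must be positive")


def day_to_generation(day: int, scale: GenerationScale | None = None) -> int:
    """Convert an experiment day to a generation count, flooring.

    ``floor(day * gens_per_day)`` with the default scale maps day 156 to
    generation 1045 and day 72 to generation 482.
    """
    if day < 0:
        raise ValueError(f"day must be non-negative, got {day}")
    scale = scale or GenerationScale()
    return math.floor(day * scale.gens_per_day)


@dataclass(frozen=True)
class MutationRecord:
    """Identity and annotation of one mutation in one population."""

    mutation_id: str
    population_id: str
    position: int
    ref_allele: str
    alt_allele: str
    mclass: str
    gene: str
    codon: int | None = None
    synonymous: bool | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.mutation_id}: position must be >= 1, got {self.position}"
            )
        if self.mclass not in MUTATION_CLASSES:
            raise ValidationError(
                f"{self.mutation_id}: unknown mutation class {self.mclass!r}"
            )
        if self.mclass == "SNP" and not (
            len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        ):
            raise ValidationError(
                f"{self.mutation_id}: SNP requires single-base ref and alt"
            )
        if self.intergenic and self.codon is not None:
            raise ValidationError(
                f"{self.mutation_id}: intergenic mutation cannot carry a codon"
            )

    @property
    def intergenic(self) -> bool:
        """True for intergenic records, labelled ``geneA/geneB``."""
        return "/" in self.gene


@dataclass(frozen=True)
class CloneGenotype:
    """One sequenced endpoint clone: ecotype label plus its mutation set."""

    clone_id: str
    population_id: str
    ecotype: str
    mutations: frozenset[str]
    extraction_day: int

    def __post_init__(self) -> None:
        if self.ecotype not in ECOTYPES:
            raise ValidationError(
                f"{self.clone_id}: unknown ecotype {self.ecotype!r}"
            )


class FrequencySeries:
    """Per-population alt/total read counts over sampled time points.

    Counts are held as two aligned DataFrames (rows = mutation ids, columns
    = sample days, ascending).  Frequencies are alt/total; where
    total == 0 the frequency is missing (NaN), never zero — an unsampled
    locus is not evidence of absence.  Float counts are permitted so that
    noise-free simulated records (exact frequencies over a large
    power-of-two denominator) fit the same container.
    """

    def __init__(
        self,
        population_id: str,
        alt: pd.DataFrame,
        total: pd.DataFrame,
        scale: GenerationScale | None = None,
    ):
        if list(alt.index) != list(total.index) or list(alt.columns) != list(
            total.columns
        ):
            raise ValidationError("alt and total tables must be aligned")
        days = [int(c) for c in alt.columns]
        if any(d < 0 for d in days):
            raise ValidationError("sample days must be non-negative")
        if days != sorted(set(days)):
            raise ValidationError("sample days must be strictly increasing")
        alt = alt.astype(float)
        alt.columns = days
        total = total.astype(float)
        total.columns = days
        if (alt.to_numpy() < 0).any() or (total.to_numpy() < 0).any():
            raise ValidationError("read counts must be non-negative")
        bad = alt.to_numpy() > total.to_numpy()
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"alt_reads > total_reads for mutation {alt.index[i]!r} "
                f"at day {days[j]}"
            )
        self.population_id = population_id
        self.alt = alt
        self.total = total
        self.scale = scale or GenerationScale()

    # -- basic views -------------------------------------------------------

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.alt.index)

    @property
    def timepoints_days(self) -> list[int]:
        return [int(c) for c in self.alt.columns]

    @property
    def timepoints_gen(self) -> list[int]:
        return [day_to_generation(d, self.scale) for d in self.timepoints_days]

    def freq(self) -> pd.DataFrame:
        """Frequency table; NaN where total_reads == 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.alt / self.total
        return f.where(self.total > 0)

    def detected(self) -> pd.DataFrame:
        """Boolean table: at least one supporting read at a sampled point."""
        return (self.alt >= 1) & (self.total > 0)

    def subset(self, mutation_ids: Sequence[str]) -> "FrequencySeries":
        keep = [m for m in self.mutation_ids if m in set(mutation_ids)]
        return FrequencySeries(
            self.population_id,
            self.alt.loc[keep].copy(),
            self.total.loc[keep].copy(),
            self.scale,
        )

    def __len__(self) -> int:
        return len(self.alt.index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FrequencySeries({self.population_id!r}, "
            f"{len(self)} mutations x {len(self.timepoints_days)} time points)"
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def _parse_day_columns(columns: Iterable[str]) -> list[int]:
    days = set()
    for c in columns:
        if c.startswith("day") and (c.endswith("_alt") or c.endswith("_total")):
            days.add(int(c[3:].rsplit("_", 1)[0]))
    return sorted(days)


def read_variant_table(
    path, scale: GenerationScale | None = None
) -> tuple[list[MutationRecord], FrequencySeries]:
    """Read the variant-table TSV dialect.

    Columns: ``population mutation_id position ref alt class gene codon
    synonymous`` then paired ``day<d>_alt`` / ``day<d>_total`` per time
    point.  Rows with malformed counts are rejected with their row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in VARIANT_META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    days = _parse_day_columns(df.columns)
    for d in days:
        for suffix in ("alt", "total"):
            if f"day{d}_{suffix}" not in df.columns:
                raise FormatError(f"{path}: unpaired count column for day {d}")

    records: list[MutationRecord] = []
    alt_rows, total_rows, index = [], [], []
    populations = set()
    for row_no, r in enumerate(df.to_dict("records"), start=2):
        codon = r["codon"].strip()
        syn = r["synonymous"].strip().lower()
        records.append(
            MutationRecord(
                mutation_id=r["mutation_id"],
                population_id=r["population"],
                position=_int_cell(r["position"], row_no, "position"),
                ref_allele=r["ref"],
                alt_allele=r["alt"],
                mclass=r["class"],
                gene=r["gene"],
                codon=int(codon) if codon else None,
                synonymous={"true": True, "false": False}.get(syn) if syn else None,
            )
        )
        populations.add(r["population"])
        alt_rows.append([_int_cell(r[f"day{d}_alt"], row_no, f"day{d}_alt") for d in days])
        total_rows.append(
            [_int_cell(r[f"day{d}_total"], row_no, f"day{d}_total") for d in days]
        )
        index.append(r["mutation_id"])
        a, t = alt_rows[-1], total_rows[-1]
        for d, av, tv in zip(days, a, t):
            if av > tv:
                raise ValidationError(
                    f"{path} row {row_no}: alt_reads ({av}) > total_reads ({tv}) "
                    f"in column day{d}_alt"
                )
    if len(populations) > 1:
        raise FormatError(f"{path}: multiple populations in one table: {populations}")
    population_id = populations.pop() if populations else ""
    series = FrequencySeries(
        population_id,
        pd.DataFrame(alt_rows, index=index, columns=days, dtype=float),
        pd.DataFrame(total_rows, index=index, columns=days, dtype=float),
        scale,
    )
    return records, series


def _int_cell(value: str, row_no: int, col: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"row {row_no}, column {col}: malformed integer {value!r}"
        ) from None


def write_variant_table(path, records: Sequence[MutationRecord], series: FrequencySeries) -> None:
    by_id = {r.mutation_id: r for r in records}
    days = series.timepoints_days
    rows = []
    for mid in series.mutation_ids:
        r = by_id[mid]
        row = {
            "population": r.population_id,
            "mutation_id": r.mutation_id,
            "position": r.position,
            "ref": r.ref_allele,
            "alt": r.alt_allele,
            "class": r.mclass,
            "gene": r.gene,
            "codon": "" if r.codon is None else r.codon,
            "synonymous": "" if r.synonymous is None else str(r.synonymous).lower(),
        }
        for d in days:
            row[f"day{d}_alt"] = _fmt_count(series.alt.at[mid, d])
            row[f"day{d}_total"] = _fmt_count(series.total.at[mid, d])
        rows.append(row)
    cols = VARIANT_META_COLUMNS + [
        f"day{d}_{s}" for d in days for s in ("alt", "total")
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _fmt_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_clone_table(path) -> list[CloneGenotype]:
    """Read the clone TSV: clone_id, population, ecotype, extraction_day,
    semicolon-separated mutation ids."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in CLONE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    clones = []
    for row_no, r in enumerate(df.to_dict("records"), start=2):
        muts = frozenset(m for m in r["mutations"].split(";") if m)
        clones.append(
            CloneGenotype(
                clone_id=r["clone_id"],
                population_id=r["population"],
                ecotype=r["ecotype"],
                mutations=muts,
                extraction_day=_int_cell(r["extraction_day"], row_no, "extraction_day"),
            )
        )
    return clones


def write_clone_table(path, clones: Sequence[CloneGenotype]) -> None:
    rows = [
        {
            "clone_id": c.clone_id,
            "population": c.population_id,
            "ecotype": c.ecotype,
            "extraction_day": c.extraction_day,
            "mutations": ";".join(sorted(c.mutations)),
        }
        for c in clones
    ]
    pd.DataFrame(rows, columns=CLONE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reporting filters
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    """Outcome of :func:`apply_reporting_filters`.

    ``series`` has masked single-read observations zeroed and failing
    mutations removed; ``single_read_mask`` marks the suppressed
    observations (aligned to the input series); ``removed`` lists the
    mutation ids dropped by the frequency/recurrence rules.
    """

    series: FrequencySeries
    single_read_mask: pd.DataFrame
    removed: list[str] = field(default_factory=list)


def single_read_mask(series: FrequencySeries) -> pd.DataFrame:
    """Boolean table of single-read observations to suppress.

    An observation with exactly one supporting read is treated as
    undetected unless the next time point carries at least two supporting
    reads.  The final time point has no successor, so a single read there
    is always suppressed.
    """
    alt = series.alt
    multi = (alt.to_numpy() >= 2)
    next_multi = np.zeros_like(multi)
    next_multi[:, :-1] = multi[:, 1:]
    return (alt == 1) & ~pd.DataFrame(next_multi, index=alt.index, columns=alt.columns)


def apply_reporting_filters(
    series: FrequencySeries,
    clones: Sequence[CloneGenotype] = (),
    min_freq: float = 0.05,
    min_samples: int = 2,
) -> FilterResult:
    """Apply the variant-reporting rules to a pooled time series.

    Masking of single-read observations happens first; the recurrence
    (detected in >= ``min_samples`` time points) and frequency (>=
    ``min_freq`` somewhere) rules are then evaluated on the masked series.
    Clone-backed mutations are always retained.
    """
    if not (0 < min_freq <= 1):
        raise ValueError(f"min_freq must lie in (0, 1], got {min_freq}")
    for c in clones:
        if c.population_id != series.population_id:
            raise ValidationError(
                f"clone {c.clone_id} belongs to population {c.population_id}, "
                f"series to {series.population_id}"
            )

    mask = single_read_mask(series)
    alt = series.alt.where(~mask, 0.0)
    masked = FrequencySeries(series.population_id, alt, series.total.copy(), series.scale)

    freq = masked.freq()
    detected = masked.detected()
    n_detected = detected.sum(axis=1)
    max_freq = freq.where(detected).max(axis=1)
    in_clones = pd.Series(
        {
            m: any(m in c.mutations for c in clones)
            for m in series.mutation_ids
        }
    )
    keep = ((n_detected >= min_samples) & (max_freq >= min_freq)) | in_clones
    kept_ids = [m for m in series.mutation_ids if keep[m]]
    removed = [m for m in series.mutation_ids if not keep[m]]
    return FilterResult(masked.subset(kept_ids), mask, removed)
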