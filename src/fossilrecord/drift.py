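"""Wright-Fisher drift null model for allele-frequency time series.

In a haploid Wright-Fisher population of effective size Ne, one generation
of pure drift adds variance pq/Ne to an allele at frequency p (q = 1 - p).
Compounded over t generations the variance is

    Var(dp) = p * q * (1 - exp(-t / Ne)),

which vanishes at t = 0 and saturates at pq as t -> infinity.  Against
this null, the observed change dp between two consecutive samples is
converted to a z-score and a normal-approximation tail probability; with
Ne of order 10^7 and intervals of order 10^2 generations, any change
beyond a fraction of a percent is astronomically unlikely under drift
alone, so surviving changes are selection (or hitchhiking) candidates.

Tail probabilities are computed in log space so that extreme z-scores
yield meaningful magnitudes instead of silently underflowing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .variants import FrequencySeries

#: Effective population size estimated for E. coli in serial batch culture.
DEFAULT_NE = 3.3e7


@dataclass(frozen=True)
class DriftParams:
    """Parameters of one drift-null evaluation.

    ne
        Effective population size (haploid individuals).
    p
        Allele frequency at the start of the interval.
    t
        Elapsed generations.
    tails
        1 for a directional test, 2 (default) for a directionless one.
    """

    p: float
    t: float
    ne: float = DEFAULT_NE
    tails: int = 2

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("Ne must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")

    @property
    def q(self) -> float:
        return 1.0 - self.p


def drift_variance(params: DriftParams) -> float:
    """Variance of the allele-frequency change after t generations of drift."""
    return params.p * params.q * -math.expm1(-params.t / params.ne)


def drift_sd(params: DriftParams) -> float:
    """Standard deviation of the drift-null frequency change."""
    return math.sqrt(drift_variance(params))


def drift_change_probability(delta: float, params: DriftParams) -> float:
    """Probability that drift alone produces a change at least as large as
    ``delta`` (normal approximation).

    Degenerate null (sd = 0, i.e. a fixed or lost allele or t = 0): any
    nonzero change has probability 0, no change has probability 1.
    """
    p_value, _ = drift_change_log10p(delta, params)
    return p_value


def drift_change_log10p(delta: float, params: DriftParams) -> tuple[float, float]:
    """As :func:`drift_change_probability`, additionally returning log10(p).

    The log-space value stays informative when the linear-scale probability
    underflows to 0.0 (z beyond ~39).
    """
    sd = drift_sd(params)
    if sd == 0.0:
        return (1.0, 0.0) if delta == 0.0 else (0.0, -math.inf)
    z = abs(delta) / sd
    log_p = norm.logsf(z) + (math.log(2.0) if params.tails == 2 else 0.0)
    log_p = min(log_p, 0.0)
    return math.exp(log_p), log_p / math.log(10.0)


@dataclass
class DriftTestResult:
    """One drift-null test for one mutation over one inter-sample interval."""

    mutation_id: str
    gen_start: int
    gen_end: int
    p_start: float
    delta: float
    variance: float
    sd: float
    z: float
    p_value: float
    log10_p: float
    adjusted_p: float = float("nan")
    selection_flag: bool = False
    degenerate: bool = False


def classify_trajectory(
    series: FrequencySeries,
    ne: float = DEFAULT_NE,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    tails: int = 2,
) -> list[DriftTestResult]:
    """Test every consecutive-interval frequency change against the drift null.

    One test per mutation per consecutive pair of time points at which its
    frequency is defined; p for the null is the frequency at the interval
    start.  Intervals with a missing frequency at either end are skipped.
    ``correction`` is ``"bonferroni"`` (m = number of tests actually
    performed in the series) or ``"none"``.  A result is flagged as a
    selection candidate when its adjusted p-value falls below ``alpha``.
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    freq = series.freq()
    gens = series.timepoints_gen
    days = series.timepoints_days
    results: list[DriftTestResult] = []
    for mid in series.mutation_ids:
        row = freq.loc[mid]
        for j in range(len(days) - 1):
            f0, f1 = row.iloc[j], row.iloc[j + 1]
            if pd.isna(f0) or pd.isna(f1):
                continue
            params = DriftParams(p=float(f0), t=gens[j + 1] - gens[j], ne=ne, tails=tails)
            var = drift_variance(params)
            sd = math.sqrt(var)
            delta = float(f1) - float(f0)
            p_value, log10_p = drift_change_log10p(delta, params)
            degenerate = sd == 0.0 and delta != 0.0
            z = abs(delta) / sd if sd > 0 else (0.0 if delta == 0.0 else math.inf)
            results.append(
                DriftTestResult(
                    mutation_id=mid,
                    gen_start=gens[j],
                    gen_end=gens[j + 1],
                    p_start=float(f0),
                    delta=delta,
                    variance=var,
                    sd=sd,
                    z=z,
                    p_value=p_value,
                    log10_p=log10_p,
                    degenerate=degenerate,
                )
            )
    m = len(results)
    for r in results:
        r.adjusted_p = min(1.0, r.p_value * m) if correction == "bonferroni" else r.p_value
        r.selection_flag = r.adjusted_p < alpha
    return results


def drift_report(results: Iterable[DriftTestResult]) -> pd.DataFrame:
    """Tabulate drift-test results for TSV export."""
    return pd.DataFrame(
        [
            {
                "mutation_id": r.mutation_id,
                "interval_start_gen": r.gen_start,
                "interval_end_gen": r.gen_end,
                "p_start": r.p_start,
                "delta": r.delta,
                "sd": r.sd,
                "z": r.z,
                "p_value": r.p_value,
                "log10_p": r.log10_p,
                "adjusted_p": r.adjusted_p,
                "flag": r.selection_flag,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
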