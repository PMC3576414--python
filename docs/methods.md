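# Methods

`fossilrecord` analyses evolve-and-resequence time series: pooled
whole-population sequencing of samples archived at intervals during a
laboratory evolution experiment (the "fossil record"), combined with
whole-genome sequencing of endpoint clones. The implementation targets
the experimental design of a serial-batch *E. coli* diversification
experiment — three replicate populations, 16 archived time points over
183 days at ~6.7 generations/day, two endpoint clones per ecotype (fast
switcher FS, slow switcher SS) per population — but every component is
parametric in those choices.

## Time scale

Days are converted to generations as `floor(day × g)` with
`g = 6.7 generations/day` by default (daily 1:100 serial transfer).
Flooring is used because it reproduces both anchor points of the
experimental design this package emulates (day 156 → generation 1045,
day 72 → generation 482); no other rounding convention does. All dating
is done on the generation axis.

## Variant reporting filters

A pooled variant table carries alt/total read counts per mutation per
time point. Frequencies at time points with zero total reads are treated
as *missing*, never as zero: an unsequenced locus is not evidence of
absence, and missing observations count as undetected in the filters.

The reporting rules, applied in this order:

1. **Single-read masking.** An observation supported by exactly one read
   is treated as undetected unless the next time point shows ≥ 2
   supporting reads. The final time point has no successor, so a single
   read there is always masked. Masked observations are zeroed in the
   output, which also makes the filter idempotent.
2. **Recurrence and frequency.** A mutation is retained when, after
   masking, it is detected (≥ 1 read) in at least `min_samples = 2` time
   points *and* reaches `min_freq = 0.05` in at least one of them.
3. **Clone rescue.** A mutation carried by any sequenced clone is
   retained regardless of its pooled frequencies.

The order of masking versus rule evaluation is genuinely ambiguous in
the source design; we mask first because a single stray read should not
count toward "detected in more than one sample". The FASTQ pre-filter
retains reads with at most 5 bases below Phred quality 20 (strict
inequality; Phred+33 encoding).

## Drift null

Under the haploid Wright–Fisher model, drift adds variance `pq/Ne` to an
allele frequency per generation; compounded over `t` generations,

    Var(Δp) = p q (1 − e^(−t/Ne)).

The sign of the exponent is fixed by the boundary behaviour (zero
variance at `t = 0`, saturation at `pq` as `t → ∞`). With the default
`Ne = 3.3 × 10⁷` (the effective size estimated for *E. coli* in similar
serial batch culture) and the 82-generation average inter-sample
interval, the fastest-drifting case `p = q = 0.5` gives a standard
deviation of ~8 × 10⁻⁴ — drift cannot plausibly move a frequency by even
1% between samples.

An observed change Δp between consecutive samples is converted to
`z = |Δp| / sd` and a normal-approximation tail probability, two-tailed
by default (a directionless "change of at least x"); one-tailed is
available. Tails are computed with `norm.logsf` in log space, so extreme
z-scores report a meaningful log10 p-value rather than silently
underflowing; the linear-scale value may still underflow to 0.0, which
is flagged by the accompanying `log10_p`. Degenerate nulls (`sd = 0` at
`p ∈ {0, 1}` or `t = 0`) return p = 0 for any nonzero change, flagged.

One test is performed per mutation per consecutive interval with defined
frequencies, with Bonferroni correction (m = tests actually performed in
the population) by default; raw p-values are always reported. The null
deliberately ignores binomial sequencing noise, matching the analysis it
reproduces; this makes the test anti-conservative at low coverage, a
known limitation.

## Clone genealogies

Clones are related under the single-origin (infinite-sites, no
reversion) assumption: a binary clone × mutation matrix admits a rooted
perfect phylogeny (ancestor all-zeros) iff no mutation pair exhibits all
three patterns {11, 10, 01} (three-gamete test). Construction groups
mutations by identical carrier sets; compatibility makes carrier sets
laminar, so containment defines the topology. Clones sharing no
mutations attach independently to the root. On conflict the default is a
loud failure carrying the full conflict report; an opt-in greedy
fallback repeatedly drops the conflicting mutation with the lowest
maximum pooled frequency (linkage miscalls in pooled data are usually
rare variants).

Dating: a mutation is dated to the midpoint between its first detection
in the (filtered) record and the previous sample (generation 0 if
detected at the first sample). A clone-borne mutation never detected in
the record is dated to the midpoint between the clone-extraction
generation and the last sample *strictly before* it, flagged
`near_end` — strictly before, because the extraction day is itself
usually a sampled day at which the mutation was not seen. Divergences
are dated midway between the last shared and first unshared mutation;
one-sided cases return the boundary of the non-empty side, flagged.
Mutations on one edge are ordered by first detection, with ties broken
by descending mean frequency, then mutation id. A mutation that
disappears and reappears in the record is dated from its first
detection only.

Independent origins of an ecotype are connected components of the
"shares ≥ 1 mutation" graph over same-ecotype clones, counted within
populations and summed (origins never merge across populations).

## Muller tables

Each mutation-carrying edge of the dated genealogy is a lineage; its
parent is the nearest mutation-carrying ancestral edge. A lineage's
frequency at a time point is summarized by its *earliest* defining
mutation (it tags the whole genetic background); a per-time-point mean
of the defining mutations is available as an alternative proxy. The
visible band width is lineage frequency minus the sum of its children's
frequencies, floored at zero; the ancestral residual is one minus the
root lineages' sum, floored likewise. All clipped mass is accumulated
and reported per time point, so band sums, residual and clipped mass
account for exactly 1. A child exceeding its parent by more than a
tolerance (default 0.05, matching binomial noise at the emulated 72 to
2,500× coverage range) is recorded as a nesting violation on the output,
never raised: pooled estimates are noisy.

Trajectory lumping (for display) is greedy single-linkage along the
within-edge order: a mutation joins the current cluster when its maximum
absolute per-time-point frequency difference to its predecessor is at
most `max_gap`; chaining is intended. `max_gap` has no default in the
CLI because it changes what the table shows. Where lineage assignment
from clones is ambiguous (mutations in no sequenced clone), the caller
assigns lineages explicitly rather than the package guessing.

## Parallelism

Each ecotype-associated mutation is scored by the finest level at which
another population carries a same-ecotype mutation at the matching
locus: identical position + alleles + class (*nucleotide*; IS-element
insertions match when element and site coincide), same gene + codon
(*codon*), same gene or intergenic label (*gene*), else *none*.
Association is derived from clone membership: a mutation carried only by
FS clones is FS-associated, and mutations carried by both ecotypes are
excluded.

The FS-vs-SS comparison is a paired t-test (scipy `ttest_rel`; the test
suite checks it against the textbook formula independently) on mean
per-clone mutation counts, one pair per FS-origin × SS-origin
combination within a population. This rule yields one comparison each
for a population with single FS and SS origins and two for a population
whose two SS clones arose independently — four comparisons for the
emulated 12-clone design.

## Synthetic data generator

The simulator is a discrete-generation Wright–Fisher model over whole
genotypes (asexual, no recombination, infinite sites — so simulated
clone matrices always admit a perfect phylogeny). Per generation,
offspring counts are multinomial with expected proportions
`x_g w_g / Σ x w`, with

    w_g = 1 + Σ s_i  (+ a_E − b_E x_E  with the ecotype model on),

new mutations arise Poisson(μNe) on frequency-weighted parents with `s`
from an exponential (default mean 0.02) or constant family, and an
ecotype-switch probability turns a mutation into an ecotype-founding
event. The linear negative frequency-dependent term is the simplest
fitness function producing stable two-ecotype coexistence (the
qualitative signature of reciprocal niche construction); it is a
stand-in for the real glucose/acetate cross-feeding ecology, not an
inference about it — the real system's frequency dependence has not been
quantified. Serial-batch population-size cycling is collapsed into a
constant `Ne`, exactly as the drift null assumes; an explicit
dilution-cycle mode is out of scope.

Sequencing is emulated as Binomial(coverage, true frequency) per
mutation per sampled day (constant or per-day coverage); infinite
coverage stores exact frequencies over a 2³⁰ denominator, which keeps
alt/total bit-exact and detection semantics identical to integer counts.
Clones are drawn by genotype frequency at the extraction day. Defaults
mirror the emulated design: 16 sampling days (0–183), 6.7
generations/day, clone day 156. Everything derives from the single
configured seed; identical configurations are bit-reproducible.

What the generator does *not* emulate: resource dynamics and diauxie,
mutation-rate heterogeneity (e.g. IS-mediated deletion hotspots),
alignment/calling artifacts, linked-read information, or coverage
variation along the genome. Passing tests therefore validate the
analysis logic and its statistical calibration, not robustness to those
real-data complications.

## Validation scales

The test suite calibrates the drift closed form against vectorized
neutral Wright–Fisher Monte Carlo (10⁵ replicate trajectories per
(Ne, t) ∈ {10³, 10⁴} × {10, 100}, agreement within 3 Monte-Carlo
standard errors using a kurtosis-robust error estimate), checks the
family-wise type-I error of the trajectory classifier on 10³ neutral
trajectories sampled at the archived schedule, verifies exact genealogy
and dating recovery on noise-free simulations at Ne = 10³ over 1,230
generations, and checks two-ecotype coexistence (≥ 95% of replicates at
Ne = 10⁴) versus fixation without frequency dependence over 60
replicates per regime. These sizes give comfortable statistical
resolution for every assertion while keeping the default test run fast.

## Known limitations

- The drift null's normal approximation degrades for p very near 0 or 1
  over short intervals; the variance itself is exact only to O(t/Ne²).
- Perfect-phylogeny reconstruction is quadratic in the number of
  mutations (pairwise three-gamete test) — ample for clone panels, not
  meant for thousands of characters.
- The greedy conflict-dropping fallback is a heuristic; with extensive
  homoplasy a likelihood-based method should be used instead.
- Lineage frequency proxies (first or mean defining mutation) are both
  biased when a lineage's defining mutations differ strongly in
  frequency; the Muller table reports, it does not de-noise.
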