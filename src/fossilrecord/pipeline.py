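"""End-to-end orchestration: filter -> genealogy -> muller -> drift -> parallelism.

Runs the full analysis over one or more per-population variant tables and
a clone table (or a simulated dataset), writing every module's output
plus a JSON run manifest.  Reruns with an identical configuration and
seed produce byte-identical outputs; the manifest records a stable hash
of the configuration, the seed, the stages executed, every output path,
and all warnings (nesting violations, phylogeny conflicts, degenerate
drift tests).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import drift as drift_mod
from . import genealogy as gen_mod
from . import muller as muller_mod
from . import parallelism as par_mod
from . import simulation as sim_mod
from . import variants as var_mod
from .errors import FossilRecordError


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    stages: list[str] = field(default_factory=list)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def config_hash(config: dict[str, Any]) -> str:
    """Stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_all(config: dict[str, Any], outdir: str | Path) -> RunManifest:
    """Execute the full pipeline.

    ``config`` keys (all optional unless noted):

    - ``variant_tables``: list of per-population variant TSV paths, and
      ``clone_table``: clone TSV path; or ``simulate``: a mapping of
      :class:`~fossilrecord.simulate.SimConfig` field overrides.
    - ``gens_per_day`` (default 6.7), ``ne`` (default 3.3e7),
      ``min_freq`` (default 0.05), ``alpha`` (default 0.05),
      ``correction`` (default "bonferroni"), ``tails`` (default 2),
      ``max_gap`` (required when ``lump`` is true), ``proxy``,
      ``drop_conflicts`` (default false), ``seed``.

    On a stage failure, partial outputs are kept and a ``MANIFEST.partial``
    marker naming the failed stage is written before the error propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    manifest = RunManifest(config_hash=config_hash(config), seed=seed)
    scale = var_mod.GenerationScale(config.get("gens_per_day", 6.7))
    stage = "setup"
    try:
        # ---- load or simulate -------------------------------------------
        stage = "input"
        datasets: list[tuple[list[var_mod.MutationRecord], var_mod.FrequencySeries]] = []
        clones: list[var_mod.CloneGenotype] = []
        if "simulate" in config:
            sim_over = dict(config["simulate"])
            eco = sim_over.pop("ecotype_model", None)
            if eco:
                sim_over["ecotype_model"] = {
                    k: sim_mod.EcotypeParams(*v) for k, v in eco.items()
                }
            if seed is not None:
                sim_over.setdefault("seed", seed)
            sim_config = sim_mod.SimConfig(
                **sim_over, gens_per_day=scale.gens_per_day
            )
            truth = sim_mod.simulate(sim_config)
            series = sim_mod.sample_fossil_record(truth, sim_config)
            clones = sim_mod.sample_clones(truth, sim_config)
            records = sim_mod.mutation_records(truth)
            datasets.append((records, series))
            var_mod.write_variant_table(outdir / "simulated_variants.tsv", records, series)
            var_mod.write_clone_table(outdir / "simulated_clones.tsv", clones)
            manifest.outputs += ["simulated_variants.tsv", "simulated_clones.tsv"]
            manifest.inputs["simulate"] = manifest.config_hash
        else:
            for p in config["variant_tables"]:
                datasets.append(var_mod.read_variant_table(p, scale))
                manifest.inputs[f"variant_table:{Path(p).name}"] = str(p)
            clones = var_mod.read_clone_table(config["clone_table"])
            manifest.inputs["clone_table"] = str(config["clone_table"])
        manifest.stages.append(stage)

        # ---- per-population stages --------------------------------------
        all_records: list[var_mod.MutationRecord] = []
        all_assoc: dict[str, str] = {}
        for records, series in datasets:
            pop = series.population_id
            pop_clones = [c for c in clones if c.population_id == pop]

            stage = "filter"
            fr = var_mod.apply_reporting_filters(
                series, pop_clones, min_freq=config.get("min_freq", 0.05)
            )
            filtered = fr.series
            kept = set(filtered.mutation_ids)
            var_mod.write_variant_table(
                outdir / f"{pop}_filtered_variants.tsv",
                [r for r in records if r.mutation_id in kept],
                filtered,
            )
            manifest.outputs.append(f"{pop}_filtered_variants.tsv")
            manifest.warnings += [
                f"{pop}: {len(fr.removed)} mutation(s) removed by reporting filters"
            ] if fr.removed else []

            stage = "genealogy"
            if pop_clones:
                tree = gen_mod.build_genealogy(
                    pop_clones,
                    filtered,
                    drop_conflicts=config.get("drop_conflicts", False),
                )
                if tree.dropped_mutations:
                    manifest.warnings.append(
                        f"{pop}: dropped conflicting mutations {tree.dropped_mutations}"
                    )
                extraction_gen = var_mod.day_to_generation(
                    pop_clones[0].extraction_day, scale
                )
                gen_mod.date_tree(tree, filtered, extraction_gen)
                (outdir / f"{pop}_genealogy.nwk").write_text(
                    gen_mod.to_newick(tree) + "\n"
                )
                gen_mod.dating_table(tree).to_csv(
                    outdir / f"{pop}_mutation_dates.tsv", sep="\t", index=False
                )
                manifest.outputs += [f"{pop}_genealogy.nwk", f"{pop}_mutation_dates.tsv"]

                stage = "muller"
                lineages = muller_mod.assign_lineages(tree, filtered)
                table = muller_mod.build_muller_table(
                    lineages,
                    filtered,
                    tolerance=config.get("tolerance", 0.05),
                    proxy=config.get("proxy", "first"),
                )
                for v in table.violations:
                    manifest.warnings.append(
                        f"{pop}: nesting violation at day {v.time_day}: "
                        f"{v.child_id} ({v.child_freq:.3f}) > {v.parent_id} "
                        f"({v.parent_freq:.3f})"
                    )
                table.to_frame(lineages, scale).to_csv(
                    outdir / f"{pop}_muller.tsv", sep="\t", index=False
                )
                manifest.outputs.append(f"{pop}_muller.tsv")

            stage = "drift"
            results = drift_mod.classify_trajectory(
                filtered,
                ne=config.get("ne", drift_mod.DEFAULT_NE),
                alpha=config.get("alpha", 0.05),
                correction=config.get("correction", "bonferroni"),
                tails=config.get("tails", 2),
            )
            n_degenerate = sum(r.degenerate for r in results)
            if n_degenerate:
                manifest.warnings.append(
                    f"{pop}: {n_degenerate} degenerate drift test(s)"
                )
            drift_mod.drift_report(results).to_csv(
                outdir / f"{pop}_drift.tsv", sep="\t", index=False
            )
            manifest.outputs.append(f"{pop}_drift.tsv")

            all_records += [r for r in records if r.mutation_id in kept]
            all_assoc.update(par_mod.ecotype_associations(records, pop_clones))
        manifest.stages += ["filter", "genealogy", "muller", "drift"]

        stage = "parallelism"
        populations = {r.population_id for r in all_records if r.mutation_id in all_assoc}
        if len(populations) >= 2:
            summary = par_mod.parallelism_levels(all_records, all_assoc)
            pairs = par_mod.independent_fs_ss_pairs(clones)
            lines = [
                f"mutations considered: {summary.n_total}",
                *(
                    f"matched at {lvl}: {summary.counts[lvl]}"
                    for lvl in par_mod.MATCH_LEVELS
                ),
                f"fraction matched at any level: {summary.fraction_matched:.3f}",
            ]
            if len(pairs) >= 2:
                cmp_ = par_mod.paired_t_test(pairs)
                lines += [
                    f"paired t (FS vs SS counts): t={cmp_.t_statistic:.4g}, "
                    f"df={cmp_.degrees_of_freedom}, p={cmp_.two_tailed_p:.4g} "
                    f"over {len(pairs)} independent comparisons",
                ]
            (outdir / "parallelism.txt").write_text("\n".join(lines) + "\n")
            pd.DataFrame(
                sorted(summary.match_level.items()),
                columns=["mutation_id", "match_level"],
            ).to_csv(outdir / "parallelism.tsv", sep="\t", index=False)
            manifest.outputs += ["parallelism.txt", "parallelism.tsv"]
            manifest.stages.append("parallelism")
        else:
            manifest.warnings.append(
                "parallelism skipped: needs ecotype-associated mutations from >= 2 populations"
            )

        (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
        manifest.outputs.append("manifest.json")
        return manifest
    except Exception as exc:
        (outdir / "MANIFEST.partial").write_text(
            f"failed at stage: {stage}\n{type(exc).__name__}: {exc}\n"
        )
        raise FossilRecordError(f"pipeline failed at stage {stage!r}: {exc}") from exc
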