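"""End-to-end pipeline: atlas classification, damage-response selection, enrichment.

Stages, in the order of the analysis they implement:

1. obtain the organ-atlas counts (simulated or from files), normalise to
   RPKM, summarise per-organ SMP expression and classify SMP genes by
   organ of origin;
2. obtain the damage-time-course counts, call per-date differential
   expression of each treated mantle library against its same-side
   control;
3. profile recurrence across dates, compare against the random-recurrence
   null, and select the persistently upregulated damaged-side genes;
4. run hypergeometric term enrichment on the selected set and on the SMP
   set.

All randomness flows from the single configured seed, so a given
configuration reproduces its output bundle byte for byte.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .config import RunConfig
from .diffexpr import call_de, de_count_table
from .enrichment import hypergeom_enrich
from .expression import (
    ExpressionThresholds,
    ValidationError,
    classify_shell_protein_origin,
    compute_rpkm,
    summarize_organ_distribution,
)
from .recurrence import (
    NullSpec,
    count_recurrence,
    excess_statistic,
    null_recurrence,
    select_persistent_genes,
)
from .synthetic import (
    AtlasScenario,
    TimeCourseScenario,
    simulate_annotations,
    simulate_damage_timecourse,
    simulate_organ_atlas,
)

__all__ = ["run_full_pipeline"]

log = logging.getLogger("shellseq")


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _load_atlas(config: RunConfig, seed: int):
    section = config.atlas
    if "scenario" in section:
        params = dict(section["scenario"])
        params.setdefault("seed", seed)
        params.setdefault("mantle_label", config.mantle_label)
        params.setdefault("hemolymph_label", config.hemolymph_label)
        scenario = AtlasScenario.from_dict(params)
        counts, truth = simulate_organ_atlas(scenario)
        smp = list(truth.smp_genes())
        return counts, smp, truth
    counts = sio.read_count_matrix(section["counts"])
    smp = sio.read_gene_list(section["smp_genes"])
    return counts, smp, None


def _load_timecourse(config: RunConfig, seed: int):
    section = config.timecourse
    if "scenario" in section:
        params = dict(section["scenario"])
        params.setdefault("seed", seed)
        scenario = TimeCourseScenario.from_dict(params)
        counts, truth = simulate_damage_timecourse(scenario)
        return counts, scenario.manifest(), truth, scenario
    counts = sio.read_count_matrix(section["counts"])
    manifest = sio.read_manifest(section["manifest"])
    return counts, manifest, None, None


def _load_annotations(config: RunConfig, gene_ids, seed: int):
    section = config.annotations
    if "simulate" in section:
        params = dict(section["simulate"])
        params.setdefault("seed", seed)
        return simulate_annotations(gene_ids, **params)
    return sio.read_annotations(section["path"], section.get("term_meta"))


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config %s (seed %d) -> %s", config.content_hash(), config.seed, out)
    atlas_seed, tc_seed, ann_seed, null_seed = _child_seeds(config.seed, 4)
    thresholds = ExpressionThresholds(
        expressed_min_rpkm=config.expressed_min_rpkm, fold_min=config.fold_min
    )
    bundle: dict = {"out_dir": out}

    with _stage("atlas"):
        atlas_counts, smp_genes, atlas_truth = _load_atlas(config, atlas_seed)
        expr = compute_rpkm(atlas_counts)
        summary = summarize_organ_distribution(expr, smp_genes, thresholds)
        classification = classify_shell_protein_origin(
            expr,
            smp_genes,
            mantle_label=config.mantle_label,
            hemolymph_label=config.hemolymph_label,
            thresholds=thresholds,
        )
        sio.write_table(summary.reset_index(), out / "organ_summary.tsv")
        sio.write_table(
            classification.table.reset_index(), out / "origin_classification.tsv"
        )
        bundle.update(
            atlas_counts=atlas_counts,
            atlas_truth=atlas_truth,
            smp_genes=smp_genes,
            expression=expr,
            organ_summary=summary,
            classification=classification,
        )

    with _stage("differential_expression"):
        tc_counts, manifest, tc_truth, tc_scenario = _load_timecourse(config, tc_seed)
        calls = call_de(tc_counts, manifest, alpha=config.alpha)
        counts_table = de_count_table(calls)
        sio.write_table(calls.table, out / "de_calls.tsv")
        sio.write_table(counts_table, out / "de_counts.tsv")
        bundle.update(
            timecourse_counts=tc_counts,
            timecourse_truth=tc_truth,
            manifest=manifest,
            calls=calls,
            de_counts=counts_table,
        )

    with _stage("recurrence"):
        sides = list(calls.dates)
        n_dates = len(calls.dates[sides[0]])
        if config.k_min > n_dates:
            raise ValidationError(
                f"k_min={config.k_min} exceeds the {n_dates} sampling dates"
            )
        hist_rows = []
        profiles = {}
        distributions = {}
        for i, side in enumerate(sides):
            for j, direction in enumerate(("up", "down")):
                profile = count_recurrence(calls, side, direction)
                mat = calls.call_matrix(side, direction)
                null = NullSpec(
                    mode=config.null_mode,
                    n_permutations=config.n_permutations,
                    seed=null_seed + 2 * i + j,
                )
                null_result = null_recurrence(len(mat), null, call_matrix=mat)
                dist = excess_statistic(profile, null_result, k_min=config.k_min)
                profiles[(side, direction)] = profile
                distributions[(side, direction)] = dist
                tab = dist.table.assign(side=side, direction=direction,
                                        tail_p=dist.tail_p)
                hist_rows.append(tab)
        hist = pd.concat(hist_rows, ignore_index=True)[
            ["side", "direction", "k", "observed", "expected", "excess",
             "observed_cum", "expected_cum", "tail_p"]
        ]
        damaged = tc_scenario.damaged_side if tc_scenario is not None else "left"
        selected = select_persistent_genes(profiles[(damaged, "up")], config.k_min)
        sio.write_table(hist, out / "recurrence.tsv")
        sio.write_gene_list(selected, out / "selected_genes.txt")
        bundle.update(
            recurrence_profiles=profiles,
            recurrence_distributions=distributions,
            recurrence_table=hist,
            selected_genes=selected,
        )

    with _stage("enrichment"):
        tc_population = list(tc_counts.gene_ids)
        atlas_population = list(atlas_counts.gene_ids)
        universe = sorted(set(tc_population) | set(atlas_population))
        annotations = _load_annotations(config, universe, ann_seed)
        enr_selected = hypergeom_enrich(list(selected), tc_population, annotations)
        enr_smp = hypergeom_enrich(list(smp_genes), atlas_population, annotations)
        sio.write_table(enr_selected.table, out / "enrichment_selected.tsv")
        sio.write_table(enr_smp.table, out / "enrichment_smp.tsv")
        bundle.update(
            annotations=annotations,
            enrichment_selected=enr_selected,
            enrichment_smp=enr_smp,
        )

    config.to_yaml(out / "run_config.yaml")
    return bundle
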