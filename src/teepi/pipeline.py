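"""End-to-end orchestration: cohort -> breakpoints -> effects -> expression.

Stages communicate through on-disk TSV/JSON artifacts so every step of the
analysis is auditable and restartable; a manifest records the exact
configuration, seed and output digests of a run.  Re-running with the same
configuration and seed reproduces byte-identical result tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breakpoints import UNIQUE, project_breakpoints
from .config import Config
from .effect_calling import (
    DEPLETION,
    ENRICHMENT,
    call_all_effects,
    effect_calls_frame,
    pair_calls_frame,
)
from .expression_link import (
    GeneModel,
    link_te_genes,
    links_frame,
    quadrant_counts,
    score_links,
    tmm_cpm,
)
from .family_stats import family_table
from .io_formats import GenomicInterval, parse_sample_names, write_results
from .null_models import PROPORTION_DOWN, positional_permutation_test, te_value_table
from .synthetic_cohort import (
    Cohort,
    CohortSpec,
    average_replicates,
    generate_cohort,
    simulate_expression,
    simulate_signal,
)

log = logging.getLogger("teepi")


@dataclass
class PipelineResult:
    breakpoints: pd.DataFrame
    pair_calls: pd.DataFrame
    effect_calls: pd.DataFrame
    links: pd.DataFrame
    quadrants: pd.DataFrame
    family_tests: pd.DataFrame
    permutation: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict


def _project_gene(gene: GeneModel, offset: int) -> GeneModel:
    iv = gene.interval
    shift = lambda feats: [(s + offset, e + offset) for s, e in feats]
    return GeneModel(
        gene.gene_id,
        GenomicInterval(iv.chrom, iv.start + offset, iv.end + offset, iv.strand),
        cds=shift(gene.cds),
        utr5=shift(gene.utr5),
        utr3=shift(gene.utr3),
    )


def run_pipeline(
    cohort_spec: CohortSpec,
    config: Config | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic cohort and return the result tables.

    Writes TSV artifacts and a manifest to ``out_dir`` when given.  Raises
    with the stage name on any stage failure.
    """
    cfg = config or Config()
    t0 = time.time()
    stage = "generate_cohort"
    try:
        cohort = generate_cohort(cohort_spec)
        log.info("cohort: %d TEs, %d genes, %d strains",
                 len(cohort.tes), len(cohort.genes), len(cohort.strains))

        stage = "breakpoints"
        calls = project_breakpoints(cohort.tes, cohort.genomes, cfg, cohort.chrom)
        bp_df = pd.DataFrame(
            [
                {
                    "te_id": c.te_id,
                    "target_strain": c.target_strain,
                    "status": c.status,
                    "position": c.position if c.position is not None else np.nan,
                    "gap_bp": c.gap_bp if c.gap_bp is not None else np.nan,
                }
                for c in calls
            ]
        )
        breakpoints = {
            (c.te_id, c.target_strain): c.position for c in calls if c.status == UNIQUE
        }
        log.info("breakpoints: %d/%d unique", len(breakpoints), len(calls))

        stage = "signal"
        tracks = simulate_signal(cohort.truth, cohort, cfg.bin_bp)
        averaged = average_replicates(tracks)
        del tracks

        stage = "effects"
        pair_calls, effect_calls = call_all_effects(
            cohort.tes, averaged, breakpoints, cohort.chrom, cfg
        )
        del averaged
        pair_df = pair_calls_frame(pair_calls)
        effect_df = effect_calls_frame(effect_calls)

        stage = "summary"
        affected = effect_df[effect_df["class"].isin([ENRICHMENT, DEPLETION])]
        if affected.empty:
            summary = pd.DataFrame(
                columns=["class", "mark", "body_part", "n_te",
                         "mean_spread_kb", "mean_percentage"]
            )
        else:
            summary = (
                affected.groupby(["class", "mark", "body_part"])
                .agg(
                    n_te=("te_id", "nunique"),
                    mean_spread_kb=("spread_kb", "mean"),
                    mean_percentage=("percentage", "mean"),
                )
                .reset_index()
            )

        stage = "expression"
        counts = simulate_expression(cohort.truth, cohort)
        meta = parse_sample_names(counts.columns)
        cpm = tmm_cpm(counts)
        tes_by_id = {te.te_id: te for te in cohort.tes}
        # linking is done in the first carrier's coordinate system
        link_calls = [ec for ec in effect_calls
                      if ec.effect in (ENRICHMENT, DEPLETION)]
        links = []
        for ec in link_calls:
            te = tes_by_id[ec.te_id]
            strain = te.carriers[0]
            iv = te.interval[strain]
            off = iv.start - cohort.truth.te_base_interval[ec.te_id][0]
            projected = [_project_gene(g, off) for g in cohort.genes]
            links.extend(
                link_te_genes([ec], tes_by_id, projected, {ec.te_id: iv}, cfg)
            )
        score_links(links, cpm, meta, tes_by_id, cfg)
        links_df = links_frame(links)
        quad_df = quadrant_counts(links)

        stage = "family_tests"
        analyzed = effect_df[effect_df["class"] != "excluded"]
        fam_by_te = {te.te_id: te.family for te in cohort.tes}
        per_te = (
            analyzed.assign(family=analyzed["te_id"].map(fam_by_te))
            .groupby(["family", "te_id"])["class"]
            .apply(lambda s: (s.isin([ENRICHMENT, DEPLETION])).any())
            .reset_index(name="has_effect")
        )
        copies = per_te.groupby("family")["te_id"].count()
        effects_n = per_te.groupby("family")["has_effect"].sum()
        if len(copies) and 0 < effects_n.sum() < per_te["te_id"].count():
            fam_df = family_table(copies, effects_n, cfg)
        else:
            fam_df = pd.DataFrame()

        stage = "permutation"
        perm_df = pd.DataFrame()
        if not links_df.empty:
            tab = te_value_table(links_df, PROPORTION_DOWN, cfg.z_threshold)
            focal = links_df.loc[
                links_df["significant"] & (links_df["direction"] == "down"), "te_id"
            ].unique().tolist()
            if focal:
                try:
                    res = positional_permutation_test(
                        tab, focal, cfg.n_permutations, cfg.rng_seed
                    )
                    perm_df = pd.DataFrame(
                        [
                            {
                                "test": "positional",
                                "statistic": PROPORTION_DOWN,
                                "observed": res.observed,
                                "n_null": res.n_null,
                                "count_ge": res.count_ge,
                                "p_value": res.p_value,
                                "seed": res.seed,
                            }
                        ]
                    )
                except ValueError as exc:
                    log.warning("positional permutation skipped: %s", exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "teepi_version": __version__,
        "seed": cohort_spec.seed,
        "config": cfg.to_dict(),
        "cohort_spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cohort_spec).items()
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    result = PipelineResult(
        bp_df, pair_df, effect_df, links_df, quad_df, fam_df, perm_df, summary, manifest
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "breakpoints.tsv": result.breakpoints,
        "pair_calls.tsv": result.pair_calls,
        "effect_calls.tsv": result.effect_calls,
        "links.tsv": result.links,
        "quadrants.tsv": result.quadrants,
        "family_tests.tsv": result.family_tests,
        "permutation.tsv": result.permutation,
        "summary.tsv": result.summary,
    }
    digests = {}
    for name, df in tables.items():
        path = out / name
        write_results(df if not df.empty else pd.DataFrame(df), path)
        digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = dict(result.manifest)
    manifest["output_digests"] = digests
    manifest["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
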