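"""End-to-end orchestration: simulate -> normalize -> score -> call ->
annotate -> expression -> integrate, with a machine-readable run report.

Every filter logs input and output counts; identical config and seed yield
an identical report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    dmr_calling,
    expression_analysis,
    genome_annotation,
    integration,
    ks_scoring,
    normalization,
    synthetic_data,
)
from .config import PipelineConfig
from .errors import ValidationError
from .io import GeneAnnotation, ProbeTrack, write_json, write_tsv

log = logging.getLogger("medipchip")


@dataclass
class SimulatedInputs:
    """Everything the generator hands to the analysis stages."""

    annotation: GeneAnnotation
    track: ProbeTrack
    methylation_truth: pd.DataFrame
    planted_dmrs: list[synthetic_data.PlantedDMR]
    expression_probes: pd.DataFrame
    expression_truth: pd.DataFrame
    se_metric: pd.Series


def simulate_inputs(config: PipelineConfig) -> SimulatedInputs:
    """Build the default synthetic profile described by the config."""
    sim = config.simulation
    spec = synthetic_data.SyntheticGenomeSpec(
        n_chromosomes=sim["n_chromosomes"],
        chrom_length=sim["chrom_length"],
        n_genes=sim["n_genes"],
        cpg_island_fraction=sim["cpg_island_fraction"],
        probe_spacing=sim["probe_spacing"],
        tile_upstream=sim["tile_upstream"],
        tile_downstream=sim["tile_downstream"],
        probe_length=sim["probe_length"],
        seed=config.seed,
    )
    annotation = synthetic_data.simulate_annotation(spec)
    probes = synthetic_data.tile_probes(annotation, spec)
    contrasts = config.contrast_pairs
    planted = synthetic_data.plant_dmrs(
        annotation,
        probes,
        n_dmrs=sim["n_planted_dmrs"],
        effect_size=sim["dmr_effect_size"],
        n_probes=sim["dmr_n_probes"],
        contrasts=contrasts,
        gain_fraction=sim["gain_fraction"],
        n_retained=sim["n_retained"],
        seed=config.seed + 1,
        tile_upstream=sim["tile_upstream"],
    )
    track, truth = synthetic_data.simulate_methylation_arrays(
        probes,
        planted,
        noise_sd=sim["noise_sd"],
        samples=list(config.samples),
        seed=config.seed + 2,
        baseline_log2=sim["baseline_log2"],
        probe_affinity_sd=sim["probe_affinity_sd"],
        ip_enrichment=sim["ip_enrichment"],
    )

    # expression ground truth: planted-DMR genes change expression (mostly
    # inversely to their methylation change), plus some unrelated genes
    rng = np.random.default_rng(config.seed + 3)
    planted_expr: list[synthetic_data.PlantedExpressionChange] = []
    seen: set[tuple[str, tuple[str, str]]] = set()
    for p in planted:
        key = (p.gene_id, p.contrast)
        if key in seen:
            continue
        seen.add(key)
        inverse = rng.random() < sim["inverse_fraction"]
        meth_up = p.direction == synthetic_data.GAIN
        sign = -1.0 if (meth_up == inverse) else 1.0
        planted_expr.append(
            synthetic_data.PlantedExpressionChange(
                transcript_id=p.gene_id,
                log2_fold_change=sign * sim["expr_log2fc"],
                contrast=p.contrast,
            )
        )
    dmr_genes = {p.gene_id for p in planted}
    others = [
        t for t in annotation.transcripts["transcript_id"] if t not in dmr_genes
    ]
    extra = rng.choice(len(others), size=min(sim["n_expression_only"], len(others)),
                       replace=False)
    for i in sorted(extra):
        contrast = contrasts[int(rng.integers(0, len(contrasts)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        planted_expr.append(
            synthetic_data.PlantedExpressionChange(
                transcript_id=others[i],
                log2_fold_change=sign * sim["expr_log2fc"],
                contrast=contrast,
            )
        )
    expr_probes, expr_truth = synthetic_data.simulate_expression(
        annotation,
        planted_expr,
        noise_sd=sim["expr_noise_sd"],
        samples=list(config.samples),
        n_probes_per_transcript=sim["n_expression_probes"],
        seed=config.seed + 4,
        se_range=tuple(sim["se_range"]),
    )
    se = expr_probes.drop_duplicates("transcript_id").set_index("transcript_id")[
        "se_metric"
    ]
    return SimulatedInputs(
        annotation=annotation,
        track=track,
        methylation_truth=truth,
        planted_dmrs=planted,
        expression_probes=expr_probes,
        expression_truth=expr_truth,
        se_metric=se,
    )


def evaluate_recovery(
    called: list[dmr_calling.DMR], truth: pd.DataFrame, contrast: tuple[str, str]
) -> dict[str, float]:
    """Sensitivity and precision against planted truth (>=1 bp overlap,
    matching direction, same contrast)."""
    label = f"{contrast[0]}:{contrast[1]}"
    planted = truth[truth["contrast"] == label]
    calls = [d for d in called if d.contrast == tuple(contrast)]

    def overlaps(d, row) -> bool:
        return (
            d.chrom == row.chrom
            and d.direction == row.direction
            and d.start <= row.end
            and row.start <= d.end
        )

    tp_truth = sum(
        any(overlaps(d, row) for d in calls) for row in planted.itertuples(index=False)
    )
    tp_calls = sum(
        any(overlaps(d, row) for row in planted.itertuples(index=False)) for d in calls
    )
    sensitivity = tp_truth / len(planted) if len(planted) else float("nan")
    precision = tp_calls / len(calls) if calls else float("nan")
    return {
        "n_planted": int(len(planted)),
        "n_called": len(calls),
        "sensitivity": sensitivity,
        "precision": precision,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages and return the run report.

    When ``outdir`` is given, all intermediate tables and the report are
    written there as TSV/BED/JSON text files.
    """
    if not config.simulation.get("enabled", True):
        raise ValidationError(
            "only the synthetic profile is wired into run_pipeline; supply "
            "pre-made tracks to the stage functions for external data"
        )
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log.info("simulate: building synthetic inputs (seed=%s)", config.seed)
    sim = simulate_inputs(config)
    track = sim.track
    log.info("simulate: %d probes x %d samples", track.n_probes, len(track.samples))

    norm_cfg = config.normalization
    track = normalization.normalize_track(
        track,
        floor=norm_cfg["floor"],
        percentile=norm_cfg["background_percentile"],
        tuning_c=norm_cfg["biweight_c"],
    )
    log.info("normalize: channels corrected, ratios centred")

    ks_cfg = config.ks
    ks_tables = {
        s: ks_scoring.score_track(
            track, s, window_bp=ks_cfg["window_bp"], max_gap_bp=ks_cfg["max_gap_bp"]
        )
        for s in track.samples
    }
    ks_all = pd.concat(ks_tables.values(), ignore_index=True)

    dmr_cfg = config.dmr
    dmrs_by_contrast: dict[tuple[str, str], list[dmr_calling.DMR]] = {}
    for contrast in config.contrast_pairs:
        a, b = contrast
        ta = dmr_calling.sample_table(track, ks_tables[a], a)
        tb = dmr_calling.sample_table(track, ks_tables[b], b)
        deltas = dmr_calling.probe_deltas(ta, tb)
        dmrs = dmr_calling.call_dmrs(
            deltas,
            contrast=contrast,
            min_probes=dmr_cfg["min_probes"],
            min_fold=dmr_cfg["min_fold"],
            min_delta_ks=dmr_cfg["min_delta_ks"],
            max_gap_bp=dmr_cfg["max_gap_bp"],
        )
        dmrs_by_contrast[contrast] = dmrs
        log.info("call-dmrs %s:%s -> %d regions", a, b, len(dmrs))

    ann_cfg = config.annotation
    bounds = genome_annotation.ClassificationBounds(
        proximal_upstream=ann_cfg["proximal_upstream"],
        proximal_downstream=ann_cfg["proximal_downstream"],
        distal_upstream=ann_cfg["distal_upstream"],
        strip_downstream=ann_cfg["strip_downstream"],
    )
    annotations = {
        c: genome_annotation.annotate_dmrs(d, sim.annotation, bounds)
        for c, d in dmrs_by_contrast.items()
    }

    expr_cfg = config.expression
    gene_map = sim.annotation.transcripts.set_index("transcript_id")["gene_symbol"]
    expr = expression_analysis.summarize_expression(
        sim.expression_probes,
        samples=list(config.samples),
        se_metric=sim.se_metric,
        gene_symbols=gene_map,
        floor=norm_cfg["floor"],
        background_percentile=norm_cfg["background_percentile"],
    )
    n_before = len(expr.table)
    expr = expression_analysis.se_filter(expr, threshold=expr_cfg["se_threshold"])
    log.info(
        "expression: se filter kept %d of %d transcripts (threshold %.2f)",
        len(expr.table), n_before, expr_cfg["se_threshold"],
    )

    int_cfg = config.integration
    de_tables = {}
    pairs_by_contrast = {}
    for contrast in config.contrast_pairs:
        de_pair = expression_analysis.call_differential(
            expr, contrast, min_fold=int_cfg["min_fold_pair"]
        )
        de_tables[contrast] = de_pair
        pairs_by_contrast[contrast] = integration.pair_dmrs_with_expression(
            annotations[contrast],
            de_pair,
            dmrs_by_contrast[contrast],
            contrast,
            min_fold=int_cfg["min_fold_pair"],
            gene_level=int_cfg["gene_level"],
        )

    primary_contrast = config.contrast_pairs[0]
    later = [dmrs_by_contrast[c] for c in config.contrast_pairs[1:]]
    retained = integration.retained_changes(dmrs_by_contrast[primary_contrast], later)
    retained_genes = sorted(
        {
            m.gene_symbol
            for d in retained
            for m in annotations[primary_contrast]
            if m.dmr_id == d.dmr_id and m.gene_symbol
        }
    )

    all_dmrs = [d for dmrs in dmrs_by_contrast.values() for d in dmrs]
    report: dict = {
        "seed": config.seed,
        "n_probes": track.n_probes,
        "samples": list(config.samples),
        "dmr_summary": dmr_calling.summarize_dmrs(all_dmrs),
        "location_distribution": {
            f"{c[0]}:{c[1]}": genome_annotation.location_distribution(a)
            for c, a in annotations.items()
        },
        "expression": {
            "n_transcripts": int(n_before),
            "n_after_se_filter": int(len(expr.table)),
            "n_differential_2fold": {
                f"{c[0]}:{c[1]}": int(
                    len(
                        expression_analysis.call_differential(
                            expr, c, min_fold=expr_cfg["min_fold_de"]
                        )
                    )
                )
                for c in config.contrast_pairs
            },
        },
        "integration": {
            f"{c[0]}:{c[1]}": {
                "n_pairs": len(pairs_by_contrast[c]),
                "n_genes_paired": len({p.gene_symbol for p in pairs_by_contrast[c]}),
                "quadrant_counts": integration.quadrant_counts(
                    pairs_by_contrast[c]
                ).to_dict(),
            }
            for c in config.contrast_pairs
        },
        "retained": {
            "n_dmrs": len(retained),
            "n_genes": len(retained_genes),
            "genes": retained_genes,
        },
        "recovery": {
            f"{c[0]}:{c[1]}": evaluate_recovery(
                dmrs_by_contrast[c], sim.methylation_truth, c
            )
            for c in config.contrast_pairs
        },
    }

    if out is not None:
        sim.annotation.write_bed(out / "transcripts.bed", out / "cpg_islands.bed")
        track.write_tsv(out / "probes_normalized.tsv")
        write_tsv(ks_all, out / "ks_scores.tsv")
        write_tsv(dmr_calling.dmrs_to_bed(all_dmrs), out / "dmrs.bed")
        write_tsv(sim.methylation_truth, out / "planted_dmrs.tsv")
        write_tsv(sim.expression_truth, out / "planted_expression.tsv")
        write_tsv(expr.table, out / "expression.tsv")
        for c, pairs in pairs_by_contrast.items():
            tag = f"{c[0]}_{c[1]}"
            write_tsv(integration.pairs_to_table(pairs), out / f"pairs_{tag}.tsv")
            _, _, coords = integration.correlation_gene_sets(pairs)
            write_tsv(coords, out / f"dotplot_{tag}.tsv")
            ann_table = genome_annotation.annotations_to_table(annotations[c])
            write_tsv(ann_table, out / f"dmr_annotations_{tag}.tsv")
        write_json(report, out / "report.json")
    return report
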