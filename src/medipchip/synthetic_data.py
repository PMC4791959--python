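"""Synthetic promoter-tiling methylation and expression arrays.

Generates an annotated toy genome, promoter-centric probe tilings
(probes concentrated upstream of each TSS), two-channel log-normal
methylation intensities with rectangular planted differential regions, and
probe-level expression intensities with planted fold changes — every
downstream stage can therefore be checked against known truth.

Signal model (log2 scale): each probe carries a sequence-affinity term
shared by both channels and all samples, the input channel is effect-free,
and the IP channel adds the planted effect for the later sample of the
planted contrast.  Per-channel Gaussian noise is ``noise_sd / sqrt(2)`` so
the per-sample log2(IP/input) ratio has standard deviation ``noise_sd`` and
a between-sample contrast difference has ``noise_sd * sqrt(2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CapacityError, PlacementError, UnknownReferenceError, ValidationError
from .io import GeneAnnotation, ProbeTrack

GAIN = "gain"
LOSS = "loss"

_GENE_LENGTH_RANGE = (2000, 8001)
_TSS_JITTER = 500
_ISLAND_LENGTH_RANGE = (300, 1001)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout parameters for the simulated genome and array design."""

    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 200
    cpg_island_fraction: float = 0.5
    probe_spacing: int = 100
    tile_upstream: int = 5000
    tile_downstream: int = 500
    probe_length: int = 50
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.probe_spacing < 1:
            raise ValidationError("probe_spacing must be >= 1")
        if not (self.tile_upstream > self.tile_downstream >= 0):
            raise ValidationError("need tile_upstream > tile_downstream >= 0")
        if not (0.0 <= self.cpg_island_fraction <= 1.0):
            raise ValidationError("cpg_island_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedDMR:
    """Ground-truth rectangular methylation change over consecutive probes."""

    gene_id: str
    chrom: str
    start: int
    end: int
    direction: str  # GAIN or LOSS in the later sample
    effect_size: float  # delta log2 ratio, > 0
    n_probes: int
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        if self.n_probes < 3:
            raise ValidationError("planted DMRs span at least 3 probes")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")
        if self.direction not in (GAIN, LOSS):
            raise ValidationError("direction must be gain or loss")


@dataclass(frozen=True)
class PlantedExpressionChange:
    """Ground-truth transcript-level log2 fold change for one contrast."""

    transcript_id: str
    log2_fold_change: float
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_fold_change):
            raise ValidationError("log2_fold_change must be finite")


def simulate_annotation(spec: SyntheticGenomeSpec) -> GeneAnnotation:
    """Place transcripts with strand, TSS and CpG islands deterministically.

    Genes are distributed round-robin over chromosomes in fixed slots wide
    enough that neighbouring promoter tiles never overlap; a capacity error
    is raised when a chromosome cannot hold its share of genes.
    """
    rng = np.random.default_rng(spec.seed)
    per_chrom = [
        spec.n_genes // spec.n_chromosomes
        + (1 if c < spec.n_genes % spec.n_chromosomes else 0)
        for c in range(spec.n_chromosomes)
    ]
    required = 2 * spec.tile_upstream + spec.tile_downstream + _TSS_JITTER + 100
    rows = []
    gi = 0
    for c, k in enumerate(per_chrom):
        if k == 0:
            continue
        chrom = f"chr{c + 1}"
        slot = spec.chrom_length // k
        if slot < required:
            raise CapacityError(
                f"{chrom}: slot of {slot} bp cannot hold a tiled gene "
                f"(needs >= {required} bp); reduce n_genes or grow the chromosome"
            )
        for i in range(k):
            gi += 1
            base = i * slot
            tss = base + spec.tile_upstream + 1 + int(rng.integers(0, _TSS_JITTER))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(*_GENE_LENGTH_RANGE))
            if strand == "+":
                start, end = tss, min(tss + length - 1, spec.chrom_length)
            else:
                start, end = max(tss - length + 1, 1), tss
            rows.append(
                {
                    "transcript_id": f"T{gi:04d}",
                    "gene_symbol": f"G{gi:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "start": start,
                    "end": end,
                }
            )
    transcripts = pd.DataFrame(rows)

    n_islands = int(round(spec.cpg_island_fraction * spec.n_genes))
    if n_islands > 0:
        chosen = rng.choice(len(transcripts), size=n_islands, replace=False)
        isl_rows = []
        for idx in sorted(chosen):
            t = transcripts.iloc[idx]
            ilen = int(rng.integers(*_ISLAND_LENGTH_RANGE))
            off = int(rng.integers(50, 1500))
            if t["strand"] == "+":
                istart = t["tss"] + off
                iend = min(istart + ilen - 1, t["end"])
            else:
                iend = t["tss"] - off
                istart = max(iend - ilen + 1, t["start"])
            if istart < iend:
                isl_rows.append({"chrom": t["chrom"], "start": istart, "end": iend})
        islands = pd.DataFrame(isl_rows, columns=["chrom", "start", "end"])
    else:
        islands = pd.DataFrame(columns=["chrom", "start", "end"])
    return GeneAnnotation(transcripts=transcripts, cpg_islands=islands)


def tile_probes(annotation: GeneAnnotation, spec: SyntheticGenomeSpec) -> pd.DataFrame:
    """Promoter-centric probe layout: every probe lies in the strand-aware
    window ``[-tile_upstream, +tile_downstream]`` around some TSS."""
    rows = []
    for t in annotation.transcripts.itertuples(index=False):
        if t.strand == "+":
            wstart = t.tss - spec.tile_upstream
            wend = t.tss + spec.tile_downstream
        else:
            wstart = t.tss - spec.tile_downstream
            wend = t.tss + spec.tile_upstream
        pos = max(wstart, 1)
        while pos + spec.probe_length - 1 <= wend:
            rows.append((t.chrom, pos, pos + spec.probe_length - 1))
            pos += spec.probe_spacing
    probes = (
        pd.DataFrame(rows, columns=["chrom", "start", "end"])
        .drop_duplicates(["chrom", "start"])
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    probes.insert(0, "probe_id", [f"P{i + 1:06d}" for i in range(len(probes))])
    return probes


def plant_dmrs(
    annotation: GeneAnnotation,
    probes: pd.DataFrame,
    n_dmrs: int,
    effect_size: float,
    n_probes: int,
    contrasts: list[tuple[str, str]],
    gain_fraction: float = 0.6,
    n_retained: int = 0,
    seed: int = 0,
    tile_upstream: int = 5000,
) -> list[PlantedDMR]:
    """Choose planted regions over consecutive probes of distinct genes.

    Contrasts are assigned round-robin.  The first ``n_retained`` genes get
    the same region and direction planted in *every* contrast (consuming
    ``len(contrasts)`` entries each of the ``n_dmrs`` budget), providing
    ground truth for retained-change detection.
    """
    rng = np.random.default_rng(seed)
    t = annotation.transcripts
    if n_retained * len(contrasts) > n_dmrs:
        raise ValidationError("n_retained * n_contrasts exceeds n_dmrs")
    n_single = n_dmrs - n_retained * len(contrasts)
    n_genes_needed = n_retained + n_single
    if n_genes_needed > len(t):
        raise CapacityError("more planted DMRs than genes")
    order = rng.permutation(len(t))[:n_genes_needed]

    by_chrom = {c: g for c, g in probes.groupby("chrom")}
    planted: list[PlantedDMR] = []

    def region_for(row) -> tuple[str, int, int]:
        chrom_probes = by_chrom[row.chrom]
        lo = row.tss - tile_upstream - 1000
        hi = row.tss + tile_upstream + 1000
        near = chrom_probes[(chrom_probes["start"] >= lo) & (chrom_probes["end"] <= hi)]
        if len(near) < n_probes:
            raise PlacementError(f"gene {row.transcript_id} has too few probes")
        k = int(rng.integers(0, len(near) - n_probes + 1))
        run = near.iloc[k : k + n_probes]
        return row.chrom, int(run["start"].iloc[0]), int(run["end"].iloc[-1])

    for j, idx in enumerate(order):
        row = t.iloc[idx]
        chrom, start, end = region_for(row)
        direction = GAIN if rng.random() < gain_fraction else LOSS
        if j < n_retained:
            for contrast in contrasts:
                planted.append(
                    PlantedDMR(
                        gene_id=row["transcript_id"], chrom=chrom, start=start,
                        end=end, direction=direction, effect_size=effect_size,
                        n_probes=n_probes, contrast=tuple(contrast),
                    )
                )
        else:
            contrast = contrasts[(j - n_retained) % len(contrasts)]
            planted.append(
                PlantedDMR(
                    gene_id=row["transcript_id"], chrom=chrom, start=start,
                    end=end, direction=direction, effect_size=effect_size,
                    n_probes=n_probes, contrast=tuple(contrast),
                )
            )
    return planted


def planted_truth_table(planted: list[PlantedDMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "direction": p.direction,
                "effect_size": p.effect_size,
                "n_probes": p.n_probes,
                "contrast": f"{p.contrast[0]}:{p.contrast[1]}",
            }
            for p in planted
        ],
        columns=[
            "gene_id", "chrom", "start", "end", "direction",
            "effect_size", "n_probes", "contrast",
        ],
    )


def simulate_methylation_arrays(
    probes: pd.DataFrame,
    planted: list[PlantedDMR],
    noise_sd: float,
    samples: list[str],
    seed: int,
    baseline_log2: float = 10.0,
    probe_affinity_sd: float = 1.0,
    ip_enrichment: float = 0.0,
) -> tuple[ProbeTrack, pd.DataFrame]:
    """Two-channel intensities with planted effects; returns (track, truth).

    The expected per-probe log2(IP/input) equals ``ip_enrichment`` plus the
    planted effect inside planted regions for the later sample of each
    planted contrast.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(probes)
    k = len(samples)
    chroms = probes["chrom"].to_numpy()
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()

    effect = np.zeros((n, k))
    for p in planted:
        if p.contrast[0] not in samples or p.contrast[1] not in samples:
            raise ValidationError(f"planted contrast {p.contrast} not in samples")
        mask = (chroms == p.chrom) & (starts <= p.end) & (ends >= p.start)
        if not mask.any():
            raise PlacementError(
                f"planted region {p.chrom}:{p.start}-{p.end} overlaps no probe"
            )
        col = samples.index(p.contrast[1])
        effect[mask, col] += p.effect_size if p.direction == GAIN else -p.effect_size

    affinity = rng.normal(0.0, probe_affinity_sd, size=n) if probe_affinity_sd > 0 else np.zeros(n)
    chan_sd = noise_sd / np.sqrt(2.0)
    log2_input = baseline_log2 + affinity[:, None] + rng.normal(0.0, 1.0, (n, k)) * chan_sd
    log2_ip = (
        baseline_log2
        + affinity[:, None]
        + ip_enrichment
        + effect
        + rng.normal(0.0, 1.0, (n, k)) * chan_sd
    )
    track = ProbeTrack(
        probes=probes.copy(),
        samples=list(samples),
        ip=np.exp2(log2_ip),
        input_=np.exp2(log2_input),
    )
    return track, planted_truth_table(planted)


def simulate_expression(
    annotation: GeneAnnotation,
    planted: list[PlantedExpressionChange],
    noise_sd: float,
    samples: list[str],
    n_probes_per_transcript: int,
    seed: int,
    baseline_log2: float = 8.0,
    baseline_sd: float = 1.0,
    probe_effect_sd: float = 0.5,
    se_range: tuple[float, float] = (0.8, 1.2),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-level expression intensities with planted fold changes.

    Returns ``(probe_table, truth_table)``; the probe table is long format
    (probe_id, transcript_id, sample, signal) plus a per-transcript
    ``se_metric`` column repeated across rows.  The per-transcript median
    polish of log2 signals recovers the planted log2 fold change in
    expectation (exactly at zero noise).
    """
    if n_probes_per_transcript < 1:
        raise ValidationError("n_probes_per_transcript must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = annotation.transcripts
    known = set(t["transcript_id"])
    fc = {}
    for p in planted:
        if p.transcript_id not in known:
            raise UnknownReferenceError(p.transcript_id)
        if p.contrast[0] not in samples or p.contrast[1] not in samples:
            raise ValidationError(f"planted contrast {p.contrast} not in samples")
        fc[(p.transcript_id, p.contrast[1])] = p.log2_fold_change

    rows = []
    se_rows = []
    for tid in t["transcript_id"]:
        base = baseline_log2 + rng.normal(0.0, 1.0) * baseline_sd
        probe_eff = rng.normal(0.0, 1.0, n_probes_per_transcript) * probe_effect_sd
        se_rows.append(
            {"transcript_id": tid, "se_metric": float(rng.uniform(*se_range))}
        )
        for i in range(n_probes_per_transcript):
            for s in samples:
                log2sig = (
                    base
                    + probe_eff[i]
                    + fc.get((tid, s), 0.0)
                    + rng.normal(0.0, 1.0) * noise_sd
                )
                rows.append(
                    {
                        "probe_id": f"{tid}_p{i + 1}",
                        "transcript_id": tid,
                        "sample": s,
                        "signal": float(np.exp2(log2sig)),
                    }
                )
    probe_table = pd.DataFrame(rows).merge(pd.DataFrame(se_rows), on="transcript_id")
    truth = pd.DataFrame(
        [
            {
                "transcript_id": p.transcript_id,
                "log2_fold_change": p.log2_fold_change,
                "contrast": f"{p.contrast[0]}:{p.contrast[1]}",
            }
            for p in planted
        ],
        columns=["transcript_id", "log2_fold_change", "contrast"],
    )
    return probe_table, truth


def simulate_cq_tables(
    methylation_by_timepoint: dict[str, float],
    expression_by_timepoint: dict[str, float],
    n_individuals: int = 3,
    n_replicates: int = 2,
    cq_sd: float = 0.1,
    efficiency: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cq tables whose expected levels match the requested ground truth.

    Methylation levels are inverted through ``1 - eff^-dCq`` and expression
    ratios through ``eff^-dCq``; replicate noise of ``cq_sd`` cycles is
    added per well.
    """
    rng = np.random.default_rng(seed)
    meth_rows, expr_rows = [], []
    log_eff = np.log(efficiency)
    for tp, level in methylation_by_timepoint.items():
        if not (level < 1.0):
            raise ValidationError("methylation level must be < 1")
        dcq = -np.log(1.0 - level) / log_eff
        for ind in range(1, n_individuals + 1):
            cq_input = 22.0 + rng.normal(0.0, 0.5)
            for rep in range(1, n_replicates + 1):
                meth_rows.append(
                    {"sample_id": f"{tp}_m{ind}", "timepoint": tp, "assay": "input",
                     "cq": cq_input + rng.normal(0.0, cq_sd), "replicate": rep}
                )
                meth_rows.append(
                    {"sample_id": f"{tp}_m{ind}", "timepoint": tp, "assay": "mcrbc",
                     "cq": cq_input + dcq + rng.normal(0.0, cq_sd), "replicate": rep}
                )
    for tp, ratio in expression_by_timepoint.items():
        if ratio <= 0:
            raise ValidationError("expression ratio must be > 0")
        dcq = -np.log(ratio) / log_eff
        for ind in range(1, n_individuals + 1):
            cq_ref = 24.0 + rng.normal(0.0, 0.5)
            for rep in range(1, n_replicates + 1):
                expr_rows.append(
                    {"sample_id": f"{tp}_m{ind}", "timepoint": tp, "assay": "reference",
                     "cq": cq_ref + rng.normal(0.0, cq_sd), "replicate": rep}
                )
                expr_rows.append(
                    {"sample_id": f"{tp}_m{ind}", "timepoint": tp, "assay": "target",
                     "cq": cq_ref + dcq + rng.normal(0.0, cq_sd), "replicate": rep}
                )
    return pd.DataFrame(meth_rows), pd.DataFrame(expr_rows)
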