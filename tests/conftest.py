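"""Shared fixtures: tiny probe tracks, a hand-enumerated classification
fixture, and a scaled-down pipeline configuration for fast end-to-end runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from medipchip.config import load_config
from medipchip.dmr_calling import DMR
from medipchip.io import GeneAnnotation, ProbeTrack


def make_track(ratios: np.ndarray, samples: list[str], chrom: str = "chr1",
               spacing: int = 100, probe_len: int = 50, start0: int = 1000,
               starts: np.ndarray | None = None) -> ProbeTrack:
    """Probe track with given log2 ratios already filled in."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.ndim == 1:
        ratios = ratios[:, None]
    n = ratios.shape[0]
    if starts is None:
        starts = start0 + spacing * np.arange(n)
    probes = pd.DataFrame(
        {
            "probe_id": [f"P{i + 1:06d}" for i in range(n)],
            "chrom": chrom,
            "start": starts,
            "end": starts + probe_len - 1,
        }
    )
    track = ProbeTrack(
        probes=probes,
        samples=samples,
        ip=np.exp2(ratios),
        input_=np.ones_like(ratios),
    )
    track.log2_ratio = ratios
    return track


def make_dmr(chrom: str, mid: int, dmr_id: str = "d", direction: str = "gain",
             width: int = 101, contrast=("d1", "d7")) -> DMR:
    """A DMR of odd width centred exactly on ``mid``."""
    half = width // 2
    return DMR(
        dmr_id=dmr_id, chrom=chrom, start=mid - half, end=mid + half,
        n_probes=3, direction=direction, contrast=contrast,
        mean_delta_ks=1.5, mean_delta_log2=1.2,
    )


@pytest.fixture
def small_config():
    """Scaled-down synthetic profile for fast pipeline tests."""
    return load_config(
        overrides={
            "seed": 7,
            "simulation": {
                "n_genes": 30,
                "chrom_length": 400_000,
                "n_planted_dmrs": 8,
                "n_retained": 1,
                "n_expression_only": 5,
            },
        }
    )


def classification_fixture():
    """Hand-enumerated 12-DMR fixture covering every location category and
    every distance boundary (+/-1 bp around +5000, +500, -100, both strands).

    Conventions under test: distances are signed strand-aware (positive =
    upstream of the TSS); proximal = [-100, +500] inclusive on both edges;
    distal = (+500, +5000]; the uncovered strip [-500, -100) maps to distal
    (flagged); intragenic = overlap with a CpG island inside a transcript
    span; intergenic = overlap with an orphan CpG island.
    """
    transcripts = pd.DataFrame(
        [
            # + strand gene on chr1: TSS at 50000, body 50000-60000
            {"transcript_id": "T0001", "gene_symbol": "G0001", "chrom": "chr1",
             "strand": "+", "tss": 50_000, "start": 50_000, "end": 60_000},
            # - strand gene on chr2: TSS at 50000, body 40000-50000
            {"transcript_id": "T0002", "gene_symbol": "G0002", "chrom": "chr2",
             "strand": "-", "tss": 50_000, "start": 40_000, "end": 50_000},
        ]
    )
    islands = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 56_000, "end": 56_500},  # inside T0001 body
            {"chrom": "chr1", "start": 200_000, "end": 200_500},  # orphan
        ]
    )
    annotation = GeneAnnotation(transcripts=transcripts, cpg_islands=islands)

    # (dmr, expected category or None, expected transcript or None)
    cases = [
        (make_dmr("chr1", 49_501, "plus_d+499"), "proximal", "T0001"),   # d=+499
        (make_dmr("chr1", 49_500, "plus_d+500"), "proximal", "T0001"),   # boundary
        (make_dmr("chr1", 49_499, "plus_d+501"), "distal", "T0001"),     # d=+501
        (make_dmr("chr1", 45_000, "plus_d+5000"), "distal", "T0001"),    # boundary
        (make_dmr("chr1", 44_999, "plus_d+5001"), None, None),           # beyond
        (make_dmr("chr1", 50_100, "plus_d-100"), "proximal", "T0001"),   # boundary
        (make_dmr("chr1", 50_101, "plus_d-101"), "distal", "T0001"),     # strip
        (make_dmr("chr2", 50_499, "minus_d+499"), "proximal", "T0002"),
        (make_dmr("chr2", 50_501, "minus_d+501"), "distal", "T0002"),
        (make_dmr("chr2", 49_900, "minus_d-100"), "proximal", "T0002"),
        (make_dmr("chr1", 56_250, "body_island"), "intragenic", "T0001"),  # d=-6250
        (make_dmr("chr1", 200_250, "orphan_island"), "intergenic", None),
    ]
    return annotation, cases
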