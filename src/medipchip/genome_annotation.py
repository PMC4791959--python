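"""Mapping of DMRs to transcripts and CpG islands.

Categories follow promoter-array conventions on the strand-aware signed
distance ``d`` from the DMR midpoint to the TSS (positive = upstream):

* proximal:   -100 <= d <= +500
* distal:     +500 <  d <= +5000
* intragenic: the DMR overlaps a CpG island contained in the transcript span
* intergenic: the DMR overlaps a CpG island that maps to no transcript

Both distance boundaries are inclusive on the proximal side, so d = +500 is
proximal and d = +5000 is distal.  The downstream strip -500 <= d < -100,
which the category definitions leave uncovered, is assigned to distal and
flagged unless the intragenic rule applies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dmr_calling import DMR
from .io import GeneAnnotation

PROXIMAL = "proximal"
DISTAL = "distal"
INTRAGENIC = "intragenic"
INTERGENIC = "intergenic"
CATEGORIES = (PROXIMAL, DISTAL, INTRAGENIC, INTERGENIC)
_PRECEDENCE = {PROXIMAL: 0, DISTAL: 1, INTRAGENIC: 2, INTERGENIC: 3}


@dataclass(frozen=True)
class ClassificationBounds:
    """Signed-distance boundaries (bp) for the location categories."""

    proximal_upstream: int = 500
    proximal_downstream: int = 100
    distal_upstream: int = 5000
    strip_downstream: int = 500


DEFAULT_BOUNDS = ClassificationBounds()


@dataclass
class DMRAnnotation:
    """One (DMR, transcript) mapping with its location category."""

    dmr_id: str
    transcript_id: str | None
    gene_symbol: str | None
    category: str
    signed_tss_distance: int | None
    flagged: bool = False


def signed_tss_distance(midpoint: int, tss: int, strand: str) -> int:
    """Strand-aware distance from a point to a TSS; positive upstream."""
    if strand == "+":
        return int(tss - midpoint)
    return int(midpoint - tss)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def classify_dmr(
    dmr: DMR,
    annotation: GeneAnnotation,
    bounds: ClassificationBounds = DEFAULT_BOUNDS,
) -> list[DMRAnnotation]:
    """All (DMR, transcript) mappings for one DMR, or a single intergenic
    mapping when the DMR overlaps only an orphan CpG island.

    Returns an empty list for a DMR with neither a transcript window nor a
    CpG-island overlap.
    """
    t = annotation.transcripts
    isl = annotation.cpg_islands
    mid = dmr.midpoint
    mappings: list[DMRAnnotation] = []
    chrom_t = t[t["chrom"] == dmr.chrom]
    chrom_isl = isl[isl["chrom"] == dmr.chrom]
    for row in chrom_t.itertuples(index=False):
        d = signed_tss_distance(mid, row.tss, row.strand)
        intragenic_island = any(
            row.start <= i.start and i.end <= row.end
            and _overlaps(dmr.start, dmr.end, i.start, i.end)
            for i in chrom_isl.itertuples(index=False)
        )
        category = None
        flagged = False
        if -bounds.proximal_downstream <= d <= bounds.proximal_upstream:
            category = PROXIMAL
        elif bounds.proximal_upstream < d <= bounds.distal_upstream:
            category = DISTAL
        elif intragenic_island:
            category = INTRAGENIC
        elif -bounds.strip_downstream <= d < -bounds.proximal_downstream:
            # uncovered strip just downstream of the proximal edge
            category = DISTAL
            flagged = True
        if category is not None:
            mappings.append(
                DMRAnnotation(
                    dmr_id=dmr.dmr_id,
                    transcript_id=row.transcript_id,
                    gene_symbol=row.gene_symbol,
                    category=category,
                    signed_tss_distance=d,
                    flagged=flagged,
                )
            )
    if not mappings:
        orphan = any(
            _overlaps(dmr.start, dmr.end, i.start, i.end)
            for i in chrom_isl.itertuples(index=False)
        )
        if orphan:
            mappings.append(
                DMRAnnotation(
                    dmr_id=dmr.dmr_id,
                    transcript_id=None,
                    gene_symbol=None,
                    category=INTERGENIC,
                    signed_tss_distance=None,
                )
            )
    return mappings


def annotate_dmrs(
    dmrs: list[DMR],
    annotation: GeneAnnotation,
    bounds: ClassificationBounds = DEFAULT_BOUNDS,
) -> list[DMRAnnotation]:
    out: list[DMRAnnotation] = []
    for d in dmrs:
        out.extend(classify_dmr(d, annotation, bounds))
    return out


def primary_annotation(mappings: list[DMRAnnotation]) -> dict[str, DMRAnnotation]:
    """One mapping per DMR: highest-precedence category, nearest TSS ties."""
    best: dict[str, DMRAnnotation] = {}
    for m in mappings:
        cur = best.get(m.dmr_id)
        key = (
            _PRECEDENCE[m.category],
            abs(m.signed_tss_distance) if m.signed_tss_distance is not None else np.inf,
        )
        if cur is None:
            best[m.dmr_id] = m
            continue
        cur_key = (
            _PRECEDENCE[cur.category],
            abs(cur.signed_tss_distance)
            if cur.signed_tss_distance is not None
            else np.inf,
        )
        if key < cur_key:
            best[m.dmr_id] = m
    return best


def location_distribution(mappings: list[DMRAnnotation]) -> dict[str, int]:
    """Category counts with each DMR counted once by its primary mapping."""
    counts = Counter(m.category for m in primary_annotation(mappings).values())
    return {c: counts.get(c, 0) for c in CATEGORIES}


def annotations_to_table(mappings: list[DMRAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dmr_id": m.dmr_id,
                "transcript_id": m.transcript_id or "",
                "gene_symbol": m.gene_symbol or "",
                "category": m.category,
                "signed_tss_distance": ""
                if m.signed_tss_distance is None
                else m.signed_tss_distance,
                "flagged": int(m.flagged),
            }
            for m in mappings
        ],
        columns=[
            "dmr_id", "transcript_id", "gene_symbol", "category",
            "signed_tss_distance", "flagged",
        ],
    )
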