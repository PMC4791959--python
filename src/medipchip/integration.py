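"""Methylome-transcriptome integration.

Pairs annotated DMRs with transcripts whose expression changes by at least a
configurable fold in the same contrast, classifies every pair into the four
(methylation direction x expression direction) quadrants stratified by
location category, and tracks regions whose methylation change persists with
the same direction across later contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .dmr_calling import DMR, GAIN
from .errors import ValidationError
from .genome_annotation import DISTAL, INTRAGENIC, PROXIMAL, DMRAnnotation

DEFAULT_PAIR_MIN_FOLD = 1.5
PAIR_CATEGORIES = (DISTAL, PROXIMAL, INTRAGENIC)

METH_UP_EXPR_UP = "meth_up_expr_up"
METH_UP_EXPR_DOWN = "meth_up_expr_down"
METH_DOWN_EXPR_UP = "meth_down_expr_up"
METH_DOWN_EXPR_DOWN = "meth_down_expr_down"
QUADRANTS = (METH_UP_EXPR_UP, METH_UP_EXPR_DOWN, METH_DOWN_EXPR_UP, METH_DOWN_EXPR_DOWN)
POSITIVE_QUADRANTS = frozenset({METH_UP_EXPR_UP, METH_DOWN_EXPR_DOWN})


@dataclass
class MethExprPair:
    """One DMR joined to one transcript's qualifying expression change."""

    dmr_id: str
    transcript_id: str
    gene_symbol: str
    location_category: str
    quadrant: str
    delta_ks: float
    log2_fc: float
    contrast: tuple[str, str]


def quadrant_of(direction: str, log2_fc: float) -> str:
    if direction == GAIN:
        return METH_UP_EXPR_UP if log2_fc > 0 else METH_UP_EXPR_DOWN
    return METH_DOWN_EXPR_UP if log2_fc > 0 else METH_DOWN_EXPR_DOWN


def pair_dmrs_with_expression(
    dmr_annotations: list[DMRAnnotation],
    de_calls: pd.DataFrame,
    dmrs: list[DMR],
    contrast: tuple[str, str],
    min_fold: float = DEFAULT_PAIR_MIN_FOLD,
    gene_level: bool = True,
) -> list[MethExprPair]:
    """One pair per (DMR mapping, transcript) with a qualifying change.

    Intergenic mappings never pair (no transcript anchor).  ``de_calls`` is
    the output of :func:`medipchip.expression_analysis.call_differential`;
    entries below ``min_fold`` are ignored so the same table can be reused
    across thresholds.  With ``gene_level=True`` the join key is the gene
    symbol, otherwise the transcript id.
    """
    by_id = {d.dmr_id: d for d in dmrs}
    for d in dmrs:
        if d.contrast != tuple(contrast):
            raise ValidationError(
                f"DMR {d.dmr_id} has contrast {d.contrast}, expected {contrast}"
            )
    thr = math.log2(min_fold)
    key = "gene_symbol" if gene_level else "transcript_id"
    fc_map: dict[str, tuple[str, str, float]] = {}
    for row in de_calls.itertuples(index=False):
        if abs(row.log2_fc) >= thr:
            fc_map[getattr(row, key)] = (row.transcript_id, row.gene_symbol, row.log2_fc)
    pairs: list[MethExprPair] = []
    for m in dmr_annotations:
        if m.category not in PAIR_CATEGORIES or m.transcript_id is None:
            continue
        hit = fc_map.get(m.gene_symbol if gene_level else m.transcript_id)
        if hit is None:
            continue
        dmr = by_id.get(m.dmr_id)
        if dmr is None:
            continue
        tid, symbol, fc = hit
        pairs.append(
            MethExprPair(
                dmr_id=m.dmr_id,
                transcript_id=tid,
                gene_symbol=symbol,
                location_category=m.category,
                quadrant=quadrant_of(dmr.direction, fc),
                delta_ks=dmr.mean_delta_ks,
                log2_fc=float(fc),
                contrast=tuple(contrast),
            )
        )
    return pairs


def quadrant_counts(pairs: list[MethExprPair]) -> pd.DataFrame:
    """Quadrant x location-category counts with a totals column."""
    table = pd.DataFrame(
        0, index=list(QUADRANTS), columns=list(PAIR_CATEGORIES) + ["total"]
    )
    for p in pairs:
        table.loc[p.quadrant, p.location_category] += 1
        table.loc[p.quadrant, "total"] += 1
    return table


def correlation_gene_sets(
    pairs: list[MethExprPair],
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Positively and inversely correlated gene lists plus dot-plot coords.

    Positive = methylation and expression move together; inverse = they move
    in opposite directions.  The coordinate table carries one row per pair
    with (delta_ks, log2_fc).
    """
    positive = sorted({p.gene_symbol for p in pairs if p.quadrant in POSITIVE_QUADRANTS})
    inverse = sorted(
        {p.gene_symbol for p in pairs if p.quadrant not in POSITIVE_QUADRANTS}
    )
    coords = pd.DataFrame(
        [
            {
                "dmr_id": p.dmr_id,
                "gene_symbol": p.gene_symbol,
                "delta_ks": p.delta_ks,
                "log2_fc": p.log2_fc,
                "quadrant": p.quadrant,
            }
            for p in pairs
        ],
        columns=["dmr_id", "gene_symbol", "delta_ks", "log2_fc", "quadrant"],
    )
    return positive, inverse, coords


def retained_changes(primary: list[DMR], later: list[list[DMR]]) -> list[DMR]:
    """DMRs from the primary contrast overlapped (>= 1 bp) by a
    same-direction DMR in every later contrast."""
    out = []
    for d in primary:
        if all(
            any(
                o.chrom == d.chrom
                and o.direction == d.direction
                and o.start <= d.end
                and d.start <= o.end
                for o in lst
            )
            for lst in later
        ):
            out.append(d)
    return out


def pairs_to_table(pairs: list[MethExprPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dmr_id": p.dmr_id,
                "transcript_id": p.transcript_id,
                "gene_symbol": p.gene_symbol,
                "location_category": p.location_category,
                "quadrant": p.quadrant,
                "delta_ks": p.delta_ks,
                "log2_fc": p.log2_fc,
                "contrast": f"{p.contrast[0]}:{p.contrast[1]}",
            }
            for p in pairs
        ],
        columns=[
            "dmr_id", "transcript_id", "gene_symbol", "location_category",
            "quadrant", "delta_ks", "log2_fc", "contrast",
        ],
    )
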