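"""Probe-set summarization and differential expression calling.

Probe intensities are background-corrected and quantile-normalized with the
shared normalization stage, log2-transformed, and summarized per transcript
with a median-polish fit of the additive model ``log2 signal = overall +
probe effect + sample effect`` (robust multi-chip style).  A per-transcript
quality metric column supports the keep-if->=-threshold filter, and fold
changes are called on the log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from . import normalization

DEFAULT_SE_THRESHOLD = 0.8
MEDIAN_POLISH_TOL = 1e-6
MEDIAN_POLISH_MAX_ITER = 10


@dataclass
class ExpressionTable:
    """Per-transcript normalized log2 signals.

    ``table`` has one row per transcript with columns ``transcript_id,
    gene_symbol, se_metric`` plus one column per sample label.
    """

    table: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in ("transcript_id", "gene_symbol") if c not in self.table]
        if missing:
            raise ValidationError(f"expression table missing {missing}")
        for s in self.samples:
            if s not in self.table.columns:
                raise ValidationError(f"missing sample column {s!r}")
        if self.table["transcript_id"].duplicated().any():
            raise ValidationError("one row per transcript required")
        self.table = self.table.reset_index(drop=True)


def rma_summarize(probe_matrix) -> np.ndarray:
    """Median-polish summary of a log2 probe x sample matrix.

    Returns ``overall + sample effects`` (one value per sample).  Iterates
    until the largest change in the residual medians drops below 1e-6, or
    ten sweeps.
    """
    x = np.asarray(probe_matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.size == 0:
        raise ValidationError("empty probe set")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite probe intensities")
    r = x.copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    for _ in range(MEDIAN_POLISH_MAX_ITER):
        rm = np.median(r, axis=1)
        r -= rm[:, None]
        row += rm
        delta = np.max(np.abs(rm)) if rm.size else 0.0
        cm = np.median(r, axis=0)
        r -= cm[None, :]
        col += cm
        delta = max(delta, np.max(np.abs(cm)))
        row_med = np.median(row)
        row -= row_med
        overall += row_med
        col_med = np.median(col)
        col -= col_med
        overall += col_med
        if delta < MEDIAN_POLISH_TOL:
            break
    return overall + col


def summarize_expression(
    probe_table: pd.DataFrame,
    samples: list[str],
    se_metric: pd.Series | None = None,
    gene_symbols: pd.Series | None = None,
    floor: float = normalization.DEFAULT_FLOOR,
    background_percentile: float = normalization.DEFAULT_BACKGROUND_PERCENTILE,
) -> ExpressionTable:
    """Normalize probe-level intensities and summarize per transcript.

    ``probe_table`` is long format with columns ``probe_id, transcript_id,
    sample, signal``.  ``se_metric`` (indexed by transcript_id) is attached
    as the quality column; transcripts without a value get 1.0.
    ``gene_symbols`` maps transcript ids to gene symbols (defaults to the
    transcript id itself).
    """
    required = {"probe_id", "transcript_id", "sample", "signal"}
    if not required <= set(probe_table.columns):
        raise ValidationError(f"probe table requires columns {sorted(required)}")
    wide = probe_table.pivot_table(
        index=["transcript_id", "probe_id"], columns="sample", values="signal"
    )[samples]
    if wide.isna().any().any():
        raise ValidationError("missing (probe, sample) intensities")
    mat = normalization.quantile_normalize(
        normalization.background_correct(
            wide.to_numpy(dtype=float), floor=floor, percentile=background_percentile
        )
    )
    log2 = np.log2(mat)
    tids = wide.index.get_level_values("transcript_id")
    rows = []
    for tid in tids.unique():
        block = log2[tids == tid]
        expr = rma_summarize(block)
        rows.append({"transcript_id": tid, **dict(zip(samples, expr))})
    table = pd.DataFrame(rows)
    if gene_symbols is not None:
        table["gene_symbol"] = (
            table["transcript_id"].map(gene_symbols).fillna(table["transcript_id"])
        )
    else:
        table["gene_symbol"] = table["transcript_id"]
    if se_metric is not None:
        table["se_metric"] = table["transcript_id"].map(se_metric).fillna(1.0)
    else:
        table["se_metric"] = 1.0
    cols = ["transcript_id", "gene_symbol", "se_metric"] + list(samples)
    return ExpressionTable(table=table[cols], samples=list(samples))


def se_filter(
    table: ExpressionTable, threshold: float = DEFAULT_SE_THRESHOLD
) -> ExpressionTable:
    """Keep transcripts whose quality metric is >= threshold."""
    if "se_metric" not in table.table.columns:
        raise ValidationError("se_metric column missing")
    kept = table.table[table.table["se_metric"] >= threshold].reset_index(drop=True)
    return ExpressionTable(table=kept, samples=list(table.samples))


def call_differential(
    table: ExpressionTable, contrast: tuple[str, str], min_fold: float
) -> pd.DataFrame:
    """Transcripts with |log2 B - log2 A| >= log2(min_fold).

    Returns columns ``transcript_id, gene_symbol, log2_fc, direction`` with
    direction ``up``/``down`` for sample B relative to sample A.  The
    boundary value is included ("at least" a fold change).
    """
    a, b = contrast
    for s in (a, b):
        if s not in table.samples:
            raise ValidationError(f"unknown sample label {s!r}")
    fc = table.table[b].to_numpy(dtype=float) - table.table[a].to_numpy(dtype=float)
    keep = np.abs(fc) >= math.log2(min_fold)
    out = table.table.loc[keep, ["transcript_id", "gene_symbol"]].copy()
    out["log2_fc"] = fc[keep]
    out["direction"] = np.where(out["log2_fc"] > 0, "up", "down")
    return out.reset_index(drop=True)
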