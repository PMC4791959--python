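"""Differential methylated region (DMR) calling between two samples.

A DMR is a maximal run of at least ``min_probes`` consecutive probes whose
between-sample log2-ratio difference is at least ``log2(min_fold)`` and whose
KS-score difference is at least ``min_delta_ks`` (gains; losses are the
mirrored condition).  Runs never bridge chromosome boundaries or inter-probe
gaps wider than ``max_gap_bp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .io import ProbeTrack
from .ks_scoring import _segment_ids

DEFAULT_MIN_PROBES = 3
DEFAULT_MIN_FOLD = 2.0
DEFAULT_MIN_DELTA_KS = 1.0
DEFAULT_MAX_GAP_BP = 500

GAIN = "gain"
LOSS = "loss"

SIZE_BINS = (500, 750, 1000)
SIZE_BIN_LABELS = ("<500", "500-750", "750-1000", ">=1000")


@dataclass
class DMR:
    """A called differentially methylated region (coordinates 1-based,
    inclusive, spanning first-probe start to last-probe end)."""

    dmr_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    direction: str  # GAIN or LOSS of sample B relative to sample A
    contrast: tuple[str, str]
    mean_delta_ks: float
    mean_delta_log2: float
    probe_ids: list[str] = field(default_factory=list)

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def probe_deltas(track_a: pd.DataFrame, track_b: pd.DataFrame) -> pd.DataFrame:
    """Per-probe differences B minus A of log2 ratio and KS score.

    Each input is a combined per-sample table with columns ``probe_id,
    chrom, start, end, log2_ratio, ks_score``, identically ordered.
    """
    for name, t in (("A", track_a), ("B", track_b)):
        missing = {"probe_id", "chrom", "start", "end", "log2_ratio", "ks_score"} - set(
            t.columns
        )
        if missing:
            raise ValidationError(f"track {name} missing columns {sorted(missing)}")
    if len(track_a) != len(track_b) or not (
        track_a["probe_id"].to_numpy() == track_b["probe_id"].to_numpy()
    ).all():
        raise AlignmentError("probe sets of the two samples do not match")
    out = track_a[["probe_id", "chrom", "start", "end"]].copy()
    out["delta_log2"] = track_b["log2_ratio"].to_numpy() - track_a["log2_ratio"].to_numpy()
    out["delta_ks"] = track_b["ks_score"].to_numpy() - track_a["ks_score"].to_numpy()
    return out


def sample_table(track: ProbeTrack, ks_table: pd.DataFrame, sample: str) -> pd.DataFrame:
    """Join a ProbeTrack's ratios with its KS scores for one sample."""
    j = track.sample_index(sample)
    out = track.probes.copy()
    out["log2_ratio"] = track.log2_ratio[:, j]
    ks = ks_table[ks_table["sample"] == sample].set_index("probe_id")
    out["ks_score"] = ks.loc[out["probe_id"], "ks_score"].to_numpy()
    return out


def call_dmrs(
    deltas: pd.DataFrame,
    contrast: tuple[str, str],
    min_probes: int = DEFAULT_MIN_PROBES,
    min_fold: float = DEFAULT_MIN_FOLD,
    min_delta_ks: float = DEFAULT_MIN_DELTA_KS,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[DMR]:
    """Return all maximal qualifying runs, gains and losses.

    A probe exactly at a threshold passes.  Probes must be sorted by
    ``(chrom, start)``.
    """
    if min_probes <= 0 or min_fold <= 0 or min_delta_ks <= 0:
        raise ValidationError("thresholds must be > 0")
    chroms = deltas["chrom"].to_numpy()
    starts = deltas["start"].to_numpy()
    ends = deltas["end"].to_numpy()
    key = pd.MultiIndex.from_arrays([chroms, starts])
    if not key.is_monotonic_increasing:
        raise ValidationError("deltas must be sorted by (chrom, start)")

    thr = math.log2(min_fold)
    dl = deltas["delta_log2"].to_numpy(dtype=float)
    dk = deltas["delta_ks"].to_numpy(dtype=float)
    seg = _segment_ids(chroms, starts, ends, max_gap_bp)
    masks = {
        GAIN: (dl >= thr) & (dk >= min_delta_ks),
        LOSS: (dl <= -thr) & (dk <= -min_delta_ks),
    }
    probe_ids = deltas["probe_id"].to_numpy()

    dmrs: list[DMR] = []
    for direction, mask in masks.items():
        ok = mask
        i = 0
        n = len(ok)
        while i < n:
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and ok[j + 1] and seg[j + 1] == seg[i]:
                j += 1
            if j - i + 1 >= min_probes:
                dmrs.append(
                    DMR(
                        dmr_id="",
                        chrom=str(chroms[i]),
                        start=int(starts[i]),
                        end=int(ends[j]),
                        n_probes=j - i + 1,
                        direction=direction,
                        contrast=contrast,
                        mean_delta_ks=float(np.mean(dk[i : j + 1])),
                        mean_delta_log2=float(np.mean(dl[i : j + 1])),
                        probe_ids=list(probe_ids[i : j + 1]),
                    )
                )
            i = j + 1
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.direction))
    tag = f"{contrast[0]}-{contrast[1]}"
    for k, d in enumerate(dmrs, start=1):
        d.dmr_id = f"{tag}.{k:04d}"
    return dmrs


def size_histogram(dmrs: list[DMR]) -> dict[str, int]:
    """Histogram of region sizes in the bins <500, 500-750, 750-1000, >=1000 bp."""
    counts = dict.fromkeys(SIZE_BIN_LABELS, 0)
    for d in dmrs:
        i = int(np.searchsorted(SIZE_BINS, d.size_bp, side="right"))
        counts[SIZE_BIN_LABELS[i]] += 1
    return counts


def summarize_dmrs(dmrs: list[DMR]) -> dict:
    """Counts by (contrast, direction) plus a size histogram."""
    by_contrast: dict[str, dict[str, int]] = {}
    for d in dmrs:
        key = f"{d.contrast[0]}:{d.contrast[1]}"
        c = by_contrast.setdefault(key, {GAIN: 0, LOSS: 0, "total": 0})
        c[d.direction] += 1
        c["total"] += 1
    return {"counts": by_contrast, "size_histogram": size_histogram(dmrs)}


def dmrs_to_bed(dmrs: list[DMR]) -> pd.DataFrame:
    """BED6+ representation (0-based half-open starts)."""
    rows = []
    for d in dmrs:
        rows.append(
            {
                "chrom": d.chrom,
                "start": d.start - 1,
                "end": d.end,
                "name": d.dmr_id,
                "score": int(np.clip(abs(d.mean_delta_ks) * 100, 0, 1000)),
                "strand": ".",
                "direction": d.direction,
                "contrast": f"{d.contrast[0]}:{d.contrast[1]}",
                "n_probes": d.n_probes,
                "mean_delta_log2": d.mean_delta_log2,
                "mean_delta_ks": d.mean_delta_ks,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "direction", "contrast", "n_probes", "mean_delta_log2", "mean_delta_ks",
        ],
    )
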