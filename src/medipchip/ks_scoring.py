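"""Signed sliding-window Kolmogorov-Smirnov scores for probe tracks.

For each probe, the log2 ratios of probes within half a window of its
midpoint (never bridging an inter-probe gap larger than ``max_gap_bp``) are
compared against the whole-sample ratio distribution with a two-sample KS
statistic.  The reported score is ``sign(median(window) - median(background))
* (-log10 p)`` with the asymptotic KS p-value at effective sample size
``n_w * n_b / (n_w + n_b)``, so a score of 1.0 corresponds to one order of
magnitude of significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .errors import ValidationError
from .io import ProbeTrack

DEFAULT_WINDOW_BP = 750
DEFAULT_MAX_GAP_BP = 500
_P_FLOOR = 1e-300  # keeps -log10(p) finite


def _ks_presorted(w: np.ndarray, b: np.ndarray) -> float:
    """KS distance between a sorted window sample and a sorted background."""
    n = w.size
    m = b.size
    k = np.arange(1, n + 1)
    right = np.searchsorted(b, w, side="right") / m
    left = np.searchsorted(b, w, side="left") / m
    d_hi = np.max(np.abs(k / n - right))
    d_lo = np.max(np.abs((k - 1) / n - left))
    return float(max(d_hi, d_lo))


def ks_statistic(window_values, background_values) -> float:
    """Two-sample KS statistic ``sup_t |ECDF_w(t) - ECDF_b(t)|``."""
    w = np.sort(np.asarray(window_values, dtype=float).ravel())
    b = np.sort(np.asarray(background_values, dtype=float).ravel())
    if w.size == 0 or b.size == 0:
        raise ValidationError("ks_statistic requires two non-empty samples")
    return _ks_presorted(w, b)


def ks_pvalue(d: float, n_window: int, n_background: int) -> float:
    """Asymptotic two-sample KS p-value at the effective sample size."""
    ne = n_window * n_background / (n_window + n_background)
    return float(kolmogorov(np.sqrt(ne) * d))


def signed_score(window_values, background_values) -> tuple[float, int]:
    """Return ``(ks_score, n_window_probes)`` for one window."""
    w = np.sort(np.asarray(window_values, dtype=float).ravel())
    b = np.sort(np.asarray(background_values, dtype=float).ravel())
    d = _ks_presorted(w, b)
    p = max(ks_pvalue(d, w.size, b.size), _P_FLOOR)
    sign = np.sign(np.median(w) - np.median(b))
    return float(sign * -np.log10(p)), int(w.size)


def _segment_ids(chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                 max_gap_bp: int) -> np.ndarray:
    """Label contiguously tiled runs: a new segment opens at a chromosome
    change or where the gap to the previous probe exceeds ``max_gap_bp``."""
    n = len(chroms)
    if n == 0:
        return np.empty(0, dtype=int)
    gap = starts[1:] - ends[:-1] - 1
    brk = (chroms[1:] != chroms[:-1]) | (gap > max_gap_bp)
    return np.concatenate([[0], np.cumsum(brk)])


def score_track(
    track: ProbeTrack,
    sample: str,
    window_bp: int = DEFAULT_WINDOW_BP,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> pd.DataFrame:
    """Score every probe of ``sample`` against the whole-sample background.

    Returns a wiggle-like table with columns ``probe_id, chrom, position,
    sample, ks_score, n_window_probes`` in track order.
    """
    if track.log2_ratio is None:
        raise ValidationError("log2 ratios not computed; normalize first")
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    j = track.sample_index(sample)
    ratios = track.log2_ratio[:, j]
    chroms = track.probes["chrom"].to_numpy()
    starts = track.probes["start"].to_numpy()
    ends = track.probes["end"].to_numpy()
    mids = track.midpoints()
    seg = _segment_ids(chroms, starts, ends, max_gap_bp)

    b = np.sort(ratios)
    n_b = b.size
    b_med = float(np.median(b))
    half = window_bp / 2.0

    scores = np.empty(track.n_probes)
    counts = np.empty(track.n_probes, dtype=int)
    # probes are sorted by (chrom, start); within a segment midpoints ascend
    for s in np.unique(seg):
        idx = np.flatnonzero(seg == s)
        m = mids[idx]
        r = ratios[idx]
        lo = np.searchsorted(m, m - half, side="left")
        hi = np.searchsorted(m, m + half, side="right")
        for k in range(idx.size):
            w = np.sort(r[lo[k]:hi[k]])
            d = _ks_presorted(w, b)
            p = max(ks_pvalue(d, w.size, n_b), _P_FLOOR)
            sign = np.sign(np.median(w) - b_med)
            scores[idx[k]] = sign * -np.log10(p)
            counts[idx[k]] = w.size
    return pd.DataFrame(
        {
            "probe_id": track.probes["probe_id"],
            "chrom": chroms,
            "position": mids,
            "sample": sample,
            "ks_score": scores,
            "n_window_probes": counts,
        }
    )
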