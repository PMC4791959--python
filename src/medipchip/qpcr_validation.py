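"""qPCR validation arithmetic.

Methylation-dependent restriction digestion: the template fraction
surviving McrBC digestion measures unmethylated DNA, so the methylation
level is ``1 - efficiency^-(Cq_mcrbc - Cq_input)``.  Expression is the
reference-normalized ratio ``efficiency^-(Cq_target - Cq_reference)``.
Group comparisons use Welch's two-sided t-test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

DEFAULT_EFFICIENCY = 2.0
ASSAYS = ("mcrbc", "input", "target", "reference")


def _check_cq(*values) -> None:
    for v in values:
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise ValidationError("non-finite Cq value")


def _check_efficiency(efficiency: float) -> None:
    if not (1.0 < efficiency <= 2.0):
        raise ValidationError("amplification efficiency must be in (1, 2]")


def methylation_level(
    cq_mcrbc: float, cq_input: float, efficiency: float = DEFAULT_EFFICIENCY
) -> float:
    """``1 - efficiency^-(cq_mcrbc - cq_input)``; may be negative.

    A negative estimate (digested template exceeding input) is reported
    as-is with a warning rather than clamped.
    """
    _check_cq(cq_mcrbc, cq_input)
    _check_efficiency(efficiency)
    level = 1.0 - efficiency ** -(cq_mcrbc - cq_input)
    if level < 0:
        warnings.warn("negative methylation estimate (McrBC/Input > 1)", stacklevel=2)
    return float(level)


def relative_expression(
    cq_target: float, cq_reference: float, efficiency: float = DEFAULT_EFFICIENCY
) -> float:
    """Reference-normalized quantity ratio ``efficiency^-(ΔCq)``."""
    _check_cq(cq_target, cq_reference)
    _check_efficiency(efficiency)
    return float(efficiency ** -(cq_target - cq_reference))


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Welch's t statistic with Satterthwaite df and the two-sided p."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def validate_cq_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "timepoint", "assay", "cq"}
    if not required <= set(table.columns):
        raise ValidationError(f"Cq table requires columns {sorted(required)}")
    if not table["assay"].isin(ASSAYS).all():
        raise ValidationError(f"assay must be one of {ASSAYS}")
    _check_cq(table["cq"].to_numpy())
    if (table["cq"] <= 0).any():
        raise ValidationError("Cq values must be > 0")
    return table


def _mean_cq(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Cq values per (sample, timepoint, assay)."""
    return (
        table.groupby(["sample_id", "timepoint", "assay"], as_index=False)["cq"]
        .mean()
        .pivot_table(index=["sample_id", "timepoint"], columns="assay", values="cq")
        .reset_index()
    )


def methylation_table(
    table: pd.DataFrame, efficiency: float = DEFAULT_EFFICIENCY
) -> pd.DataFrame:
    """Per-individual methylation levels from a Cq table."""
    wide = _mean_cq(validate_cq_table(table))
    for col in ("mcrbc", "input"):
        if col not in wide.columns:
            raise ValidationError(f"missing {col!r} assay rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wide["level"] = [
            methylation_level(m, i, efficiency)
            for m, i in zip(wide["mcrbc"], wide["input"])
        ]
    return wide[["sample_id", "timepoint", "level"]]


def expression_table(
    table: pd.DataFrame, efficiency: float = DEFAULT_EFFICIENCY
) -> pd.DataFrame:
    """Per-individual reference-normalized expression from a Cq table."""
    wide = _mean_cq(validate_cq_table(table))
    for col in ("target", "reference"):
        if col not in wide.columns:
            raise ValidationError(f"missing {col!r} assay rows")
    wide["level"] = [
        relative_expression(t, r, efficiency)
        for t, r in zip(wide["target"], wide["reference"])
    ]
    return wide[["sample_id", "timepoint", "level"]]


def compare_timepoints(levels: pd.DataFrame, timepoint_a: str, timepoint_b: str
                       ) -> dict[str, float]:
    """Welch test of per-individual levels between two timepoints."""
    a = levels.loc[levels["timepoint"] == timepoint_a, "level"]
    b = levels.loc[levels["timepoint"] == timepoint_b, "level"]
    t, p = group_compare(a, b)
    return {
        "timepoint_a": timepoint_a,
        "timepoint_b": timepoint_b,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": t,
        "p": p,
    }
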