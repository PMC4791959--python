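"""Pipeline configuration.

A single flat YAML file with stage sections; every stage parameter is
surfaced with its default so that deviations are auditable.  Defaults match
the published analysis parameters: 750 bp KS window, 500 bp maximum
inter-probe spacing, >=3 consecutive probes, >=2-fold methylation change
with a KS-score difference >=1.0, 2-fold expression calls, 1.5-fold pairing
threshold, and the 0.8 quality-metric cutoff.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

DEFAULTS: dict = {
    "seed": 42,
    "samples": ["d1", "d7", "w2", "w8"],
    "contrasts": [["d1", "d7"], ["d1", "w2"], ["d1", "w8"]],
    "simulation": {
        "enabled": True,
        "n_chromosomes": 2,
        "chrom_length": 2_000_000,
        "n_genes": 200,
        "cpg_island_fraction": 0.5,
        "probe_spacing": 100,
        "tile_upstream": 5000,
        "tile_downstream": 500,
        "probe_length": 50,
        "n_planted_dmrs": 50,
        "dmr_effect_size": 1.5,
        "dmr_n_probes": 4,
        "gain_fraction": 0.6,
        "n_retained": 4,
        "noise_sd": 0.3,
        "baseline_log2": 10.0,
        "probe_affinity_sd": 1.0,
        "ip_enrichment": 0.0,
        "n_expression_probes": 3,
        "expr_noise_sd": 0.2,
        "expr_log2fc": 1.0,
        "inverse_fraction": 0.7,
        "n_expression_only": 20,
        "se_range": [0.8, 1.2],
    },
    # The synthetic intensities carry no additive scanner background, so the
    # profile uses a near-minimum percentile; the standalone normalize stage
    # defaults to the 5th percentile for real arrays.
    "normalization": {
        "background_percentile": 0.5,
        "floor": 1.0,
        "biweight_c": 5.0,
    },
    "ks": {"window_bp": 750, "max_gap_bp": 500},
    "dmr": {"min_probes": 3, "min_fold": 2.0, "min_delta_ks": 1.0, "max_gap_bp": 500},
    "annotation": {
        "proximal_upstream": 500,
        "proximal_downstream": 100,
        "distal_upstream": 5000,
        "strip_downstream": 500,
    },
    "expression": {"se_threshold": 0.8, "min_fold_de": 2.0},
    "integration": {"min_fold_pair": 1.5, "gene_level": True},
    "qpcr": {"efficiency": 2.0},
    "paths": {"outdir": "results"},
}


@dataclass
class PipelineConfig:
    """Validated configuration tree; access sections as attributes."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __post_init__(self) -> None:
        for key, value in (
            ("ks.window_bp", self.ks["window_bp"]),
            ("dmr.min_probes", self.dmr["min_probes"]),
            ("dmr.min_fold", self.dmr["min_fold"]),
            ("dmr.min_delta_ks", self.dmr["min_delta_ks"]),
            ("expression.min_fold_de", self.expression["min_fold_de"]),
            ("integration.min_fold_pair", self.integration["min_fold_pair"]),
        ):
            if value <= 0:
                raise ValidationError(f"{key} must be > 0, got {value}")
        for c in self.contrasts:
            if len(c) != 2 or any(s not in self.samples for s in c):
                raise ValidationError(f"bad contrast {c}")

    def __getattr__(self, name: str):
        try:
            return self.data[name]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def contrast_pairs(self) -> list[tuple[str, str]]:
        return [tuple(c) for c in self.contrasts]


def _deep_update(base: dict, override: dict) -> dict:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> PipelineConfig:
    """Merge defaults <- YAML file <- explicit overrides."""
    data = copy.deepcopy(DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValidationError("config file must contain a mapping")
        _deep_update(data, loaded)
    if overrides:
        _deep_update(data, overrides)
    return PipelineConfig(data=data)


def write_default_config(path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(copy.deepcopy(DEFAULTS), sort_keys=False))
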