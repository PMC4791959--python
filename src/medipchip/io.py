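"""Core containers and plain-text I/O.

All genomic coordinates are 1-based and inclusive internally.  BED output is
converted to the conventional 0-based half-open form on write and converted
back on read.  Every on-disk format is uncompressed, tab-separated text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end"]


@dataclass
class ProbeTrack:
    """Genomically located tiling probes with per-sample channel intensities.

    Parameters
    ----------
    probes
        One row per probe with columns ``probe_id, chrom, start, end``,
        sorted by ``(chrom, start)``.
    samples
        Ordered sample labels (e.g. ``["d1", "d7", "w2", "w8"]``).
    ip, input_
        Intensity matrices of shape ``(n_probes, n_samples)`` for the
        immunoprecipitated and input channels.
    log2_ratio
        Per-probe, per-sample centred log2(IP/input) ratios; ``None`` until
        filled by the normalization stage.
    """

    probes: pd.DataFrame
    samples: list[str]
    ip: np.ndarray
    input_: np.ndarray
    log2_ratio: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        n = len(self.probes)
        for name, mat in (("ip", self.ip), ("input", self.input_)):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (n, len(self.samples)):
                raise ValidationError(
                    f"{name} matrix shape {mat.shape} does not match "
                    f"{n} probes x {len(self.samples)} samples"
                )
        self.ip = np.asarray(self.ip, dtype=float)
        self.input_ = np.asarray(self.input_, dtype=float)
        if (self.probes["start"] > self.probes["end"]).any():
            raise ValidationError("probe with start > end")
        if not self._is_sorted():
            raise ValidationError("probes must be sorted by (chrom, start)")

    def _is_sorted(self) -> bool:
        p = self.probes
        key = pd.MultiIndex.from_arrays([p["chrom"], p["start"]])
        return key.is_monotonic_increasing

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ValidationError(f"unknown sample label {sample!r}") from None

    def midpoints(self) -> np.ndarray:
        return (self.probes["start"].to_numpy() + self.probes["end"].to_numpy()) / 2.0

    def copy(self) -> "ProbeTrack":
        return ProbeTrack(
            probes=self.probes.copy(),
            samples=list(self.samples),
            ip=self.ip.copy(),
            input_=self.input_.copy(),
            log2_ratio=None if self.log2_ratio is None else self.log2_ratio.copy(),
        )

    # ------------------------------------------------------------------ I/O
    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per (probe, sample)."""
        frames = []
        for j, s in enumerate(self.samples):
            f = self.probes[PROBE_COLUMNS].copy()
            f["sample"] = s
            f["ip_signal"] = self.ip[:, j]
            f["input_signal"] = self.input_[:, j]
            if self.log2_ratio is not None:
                f["log2_ratio"] = self.log2_ratio[:, j]
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def write_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "ProbeTrack":
        required = PROBE_COLUMNS + ["sample", "ip_signal", "input_signal"]
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValidationError(f"probe table missing columns: {missing}")
        samples = list(dict.fromkeys(table["sample"]))
        probes = (
            table.loc[table["sample"] == samples[0], PROBE_COLUMNS]
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )
        n = len(probes)
        ip = np.empty((n, len(samples)))
        inp = np.empty((n, len(samples)))
        ratio = np.empty((n, len(samples))) if "log2_ratio" in table.columns else None
        order = probes["probe_id"]
        for j, s in enumerate(samples):
            sub = table[table["sample"] == s].set_index("probe_id")
            sub = sub.loc[order]
            ip[:, j] = sub["ip_signal"].to_numpy(dtype=float)
            inp[:, j] = sub["input_signal"].to_numpy(dtype=float)
            if ratio is not None:
                ratio[:, j] = sub["log2_ratio"].to_numpy(dtype=float)
        return cls(probes=probes, samples=samples, ip=ip, input_=inp, log2_ratio=ratio)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProbeTrack":
        return cls.from_long(pd.read_csv(path, sep="\t"))


@dataclass
class GeneAnnotation:
    """TSS-bearing transcript records plus CpG-island intervals.

    ``transcripts`` columns: transcript_id, gene_symbol, chrom, strand, tss,
    start, end.  ``cpg_islands`` columns: chrom, start, end.
    """

    transcripts: pd.DataFrame
    cpg_islands: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def __post_init__(self) -> None:
        t = self.transcripts
        if len(t):
            if not t["strand"].isin(["+", "-"]).all():
                raise ValidationError("strand must be '+' or '-'")
            bad = (t["tss"] < t["start"]) | (t["tss"] > t["end"])
            if bad.any():
                raise ValidationError("TSS outside transcript span")
        self.transcripts = t.reset_index(drop=True)
        self.cpg_islands = self.cpg_islands.reset_index(drop=True)

    def write_bed(self, transcripts_path: str | Path, islands_path: str | Path) -> None:
        t = self.transcripts
        bed = pd.DataFrame(
            {
                "chrom": t["chrom"],
                "start": t["start"] - 1,
                "end": t["end"],
                "name": t["transcript_id"] + "|" + t["gene_symbol"],
                "score": 0,
                "strand": t["strand"],
            }
        )
        bed.to_csv(transcripts_path, sep="\t", index=False, header=False)
        isl = self.cpg_islands
        pd.DataFrame(
            {
                "chrom": isl["chrom"],
                "start": isl["start"] - 1,
                "end": isl["end"],
                "name": [f"CGI_{i:05d}" for i in range(len(isl))],
            }
        ).to_csv(islands_path, sep="\t", index=False, header=False)

    @classmethod
    def read_bed(
        cls, transcripts_path: str | Path, islands_path: str | Path | None = None
    ) -> "GeneAnnotation":
        bed = pd.read_csv(
            transcripts_path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        ids = bed["name"].str.split("|", expand=True)
        start = bed["start"] + 1
        tss = np.where(bed["strand"] == "+", start, bed["end"])
        transcripts = pd.DataFrame(
            {
                "transcript_id": ids[0],
                "gene_symbol": ids[1] if ids.shape[1] > 1 else ids[0],
                "chrom": bed["chrom"],
                "strand": bed["strand"],
                "tss": tss,
                "start": start,
                "end": bed["end"],
            }
        )
        if islands_path is not None and Path(islands_path).exists():
            isl = pd.read_csv(
                islands_path,
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "name"],
            )
            islands = pd.DataFrame(
                {"chrom": isl["chrom"], "start": isl["start"] + 1, "end": isl["end"]}
            )
        else:
            islands = pd.DataFrame(columns=["chrom", "start", "end"])
        return cls(transcripts=transcripts, cpg_islands=islands)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
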