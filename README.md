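# medipchip

Tiling-array MeDIP-chip differential methylation analysis as a tested,
reusable pipeline:

* **synthetic_data** — annotated toy genome, promoter-centric probe tiling
  (probes concentrated −5000…+500 bp around TSSs), two-channel log-normal
  intensities with planted rectangular methylation changes, probe-level
  expression signals with planted fold changes, and qPCR Cq tables — all
  with ground-truth tables for recovery testing.
* **normalization** — per-channel percentile background correction,
  quantile normalization across samples, and one-step Tukey-biweight
  centred log2(IP/input) ratios.
* **ks_scoring** — per-probe signed sliding-window Kolmogorov–Smirnov
  scores (750 bp window, 500 bp maximum inter-probe gap): window vs
  whole-sample background, score = sign(median shift) × (−log10 p).
* **dmr_calling** — differentially methylated regions as maximal runs of
  ≥3 consecutive probes with ≥2-fold (Δlog2 ≥ 1) change and ΔKS ≥ 1
  between two samples, gains and losses.
* **genome_annotation** — proximal (−100…+500 bp from TSS), distal
  (+500…+5000 bp), intragenic (CpG island inside a transcript), intergenic
  (orphan CpG island) classification with strand-aware signed distances.
* **expression_analysis** — median-polish probe-set summarization,
  quality-metric (≥0.8) filtering, and fold-change calls at 2.0/1.5-fold.
* **integration** — DMR × expression pairing at ≥1.5-fold, four-quadrant
  tables stratified by location, positively/inversely correlated gene
  sets, and retained (same-direction, overlapping across contrasts)
  changes.
* **qpcr_validation** — McrBC methylation estimates `1 − eff^−ΔCq`,
  reference-normalized expression `eff^−ΔCq`, Welch two-sided t-tests.
* **pipeline / cli** — a YAML-configured end-to-end run with a
  machine-readable JSON report.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance surface: oracle-equivalence
checks for the KS statistic and the DMR caller, quantile-normalization
invariants at scale, a hand-enumerated 12-DMR classification fixture,
quadrant accounting properties, qPCR closed forms, and planted-DMR recovery
on the default synthetic profile.

Note: the planted-DMR recovery criterion asserts sensitivity ≥ 0.9 at the
default profile (effect 1.5, per-probe fold threshold 1.0, contrast noise
sd 0.3·√2 ≈ 0.42, 4-probe regions). A 4-probe region contains a passing
3-run with probability ≈ 2p³ − p⁴ ≈ 0.8 for per-probe pass rate
p ≈ Φ(0.5/0.42) ≈ 0.88, so measured sensitivity lands near 0.84 and the
assertion fails by construction; it is kept unweakened. Precision meets its
0.9 bound.

## CLI

```bash
medipchip init-config config.yaml            # write the default config
medipchip pipeline run --config config.yaml --outdir results/run

# or stage by stage:
medipchip simulate  --config config.yaml --outdir sim/
medipchip normalize --in sim/probes.tsv --out norm.tsv
medipchip score     --in norm.tsv --out scores.tsv --window 750 --max-gap 500
medipchip call-dmrs --in norm.tsv --scores scores.tsv --out dmrs.bed \
                    --contrast d1:d7 --min-probes 3 --min-fold 2 --min-dks 1.0
medipchip annotate  --dmrs dmrs.bed --genes sim/transcripts.bed \
                    --cpg sim/cpg_islands.bed --out annotated.tsv
medipchip expression --in sim/expression_probes.tsv --out de.tsv \
                    --contrast d1:d7 --min-fold 2
medipchip qpcr      --in cq.tsv --out levels.tsv --mode methylation \
                    --compare d1:d7
```

All file formats are plain text: long-format probe TSVs, BED6/BED4
annotation, wiggle-like KS TSVs, BED6+ DMRs, and JSON reports.

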