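import numpy as np
import pandas as pd
import pytest

from medipchip import synthetic_data as sd
from medipchip.errors import (
    CapacityError,
    PlacementError,
    UnknownReferenceError,
    ValidationError,
)
from medipchip.expression_analysis import rma_summarize

SAMPLES = ["d1", "d7", "w2", "w8"]


def small_spec(**kw):
    defaults = dict(n_chromosomes=1, chrom_length=400_000, n_genes=10, seed=42)
    defaults.update(kw)
    return sd.SyntheticGenomeSpec(**defaults)


class TestSpecInvariants:
    def test_bad_gene_count(self):
        with pytest.raises(ValidationError):
            small_spec(n_genes=0)

    def test_bad_spacing(self):
        with pytest.raises(ValidationError):
            small_spec(probe_spacing=0)

    def test_bad_tiling(self):
        with pytest.raises(ValidationError):
            small_spec(tile_upstream=500, tile_downstream=500)


class TestAnnotation:
    def test_exact_transcript_count(self):
        ann = sd.simulate_annotation(small_spec(n_genes=10, seed=42))
        assert len(ann.transcripts) == 10

    def test_zero_island_fraction(self):
        ann = sd.simulate_annotation(small_spec(cpg_island_fraction=0.0))
        assert len(ann.cpg_islands) == 0

    def test_determinism_byte_identical(self, tmp_path):
        spec = small_spec(n_genes=20, seed=7, cpg_island_fraction=0.5)
        paths = []
        for tag in ("a", "b"):
            ann = sd.simulate_annotation(spec)
            tp = tmp_path / f"t_{tag}.bed"
            ip = tmp_path / f"i_{tag}.bed"
            ann.write_bed(tp, ip)
            paths.append((tp.read_bytes(), ip.read_bytes()))
        assert paths[0] == paths[1]

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            sd.simulate_annotation(small_spec(chrom_length=50_000, n_genes=10))

    def test_transcripts_within_bounds_and_tss_in_span(self):
        spec = small_spec(n_genes=30, chrom_length=600_000, seed=3)
        ann = sd.simulate_annotation(spec)
        t = ann.transcripts
        assert (t["start"] >= 1).all()
        assert (t["end"] <= spec.chrom_length).all()
        assert ((t["tss"] >= t["start"]) & (t["tss"] <= t["end"])).all()
        assert set(t["strand"]) <= {"+", "-"}

    def test_islands_within_transcripts(self):
        ann = sd.simulate_annotation(small_spec(n_genes=20, seed=9))
        t = ann.transcripts
        for isl in ann.cpg_islands.itertuples(index=False):
            inside = (
                (t["chrom"] == isl.chrom)
                & (t["start"] <= isl.start)
                & (t["end"] >= isl.end)
            )
            assert inside.any()


class TestProbeTiling:
    def test_full_promoter_coverage(self):
        """Every probe lies in the strand-aware TSS window of some gene."""
        spec = small_spec(n_genes=12, seed=5)
        ann = sd.simulate_annotation(spec)
        probes = sd.tile_probes(ann, spec)
        covered = np.zeros(len(probes), dtype=bool)
        for t in ann.transcripts.itertuples(index=False):
            if t.strand == "+":
                lo, hi = t.tss - spec.tile_upstream, t.tss + spec.tile_downstream
            else:
                lo, hi = t.tss - spec.tile_downstream, t.tss + spec.tile_upstream
            covered |= (
                (probes["chrom"] == t.chrom).to_numpy()
                & (probes["start"] >= lo).to_numpy()
                & (probes["end"] <= hi).to_numpy()
            )
        assert covered.all()

    def test_probes_sorted_unique(self):
        spec = small_spec(n_genes=12, seed=5)
        probes = sd.tile_probes(sd.simulate_annotation(spec), spec)
        key = pd.MultiIndex.from_arrays([probes["chrom"], probes["start"]])
        assert key.is_monotonic_increasing
        assert not key.duplicated().any()


class TestMethylationArrays:
    def _setup(self, **spec_kw):
        spec = small_spec(**spec_kw)
        ann = sd.simulate_annotation(spec)
        probes = sd.tile_probes(ann, spec)
        return spec, ann, probes

    def _plant_one(self, ann, probes, effect=1.5, n_probes=4, direction="gain"):
        t = ann.transcripts.iloc[0]
        near = probes[probes["chrom"] == t["chrom"]].iloc[:n_probes]
        return sd.PlantedDMR(
            gene_id=t["transcript_id"], chrom=t["chrom"],
            start=int(near["start"].iloc[0]), end=int(near["end"].iloc[-1]),
            direction=direction, effect_size=effect, n_probes=n_probes,
            contrast=("d1", "d7"),
        )

    def test_zero_noise_planted_exact(self):
        spec, ann, probes = self._setup()
        planted = [self._plant_one(ann, probes)]
        track, truth = sd.simulate_methylation_arrays(
            probes, planted, noise_sd=0.0, samples=SAMPLES, seed=1
        )
        raw = np.log2(track.ip) - np.log2(track.input_)
        diff = raw[:, SAMPLES.index("d7")] - raw[:, SAMPLES.index("d1")]
        p = planted[0]
        inside = (
            (track.probes["chrom"] == p.chrom)
            & (track.probes["start"] <= p.end)
            & (track.probes["end"] >= p.start)
        ).to_numpy()
        np.testing.assert_allclose(diff[inside], 1.5, atol=1e-9)
        np.testing.assert_allclose(diff[~inside], 0.0, atol=1e-9)
        assert len(truth) == 1

    def test_no_planted_zero_noise_all_zero(self):
        spec, ann, probes = self._setup()
        track, truth = sd.simulate_methylation_arrays(
            probes, [], noise_sd=0.0, samples=SAMPLES, seed=1
        )
        raw = np.log2(track.ip) - np.log2(track.input_)
        np.testing.assert_allclose(raw.max() - raw.min(), 0.0, atol=1e-9)
        assert truth.empty

    def test_null_contrast_mean_clt_bound(self):
        spec, ann, probes = self._setup(
            n_genes=200, n_chromosomes=2, chrom_length=2_000_000
        )
        noise_sd = 0.3
        track, _ = sd.simulate_methylation_arrays(
            probes, [], noise_sd=noise_sd, samples=SAMPLES, seed=42
        )
        n = track.n_probes
        assert n >= 10_000
        raw = np.log2(track.ip) - np.log2(track.input_)
        diff = raw[:, 1] - raw[:, 0]
        bound = 3 * (noise_sd * np.sqrt(2)) / np.sqrt(n)
        assert abs(diff.mean()) < bound

    def test_contrast_sd_matches_model(self):
        spec, ann, probes = self._setup(
            n_genes=200, n_chromosomes=2, chrom_length=2_000_000
        )
        track, _ = sd.simulate_methylation_arrays(
            probes, [], noise_sd=0.3, samples=SAMPLES, seed=11
        )
        raw = np.log2(track.ip) - np.log2(track.input_)
        diff = raw[:, 1] - raw[:, 0]
        assert diff.std() == pytest.approx(0.3 * np.sqrt(2), rel=0.05)

    def test_truth_consistency_thresholds(self):
        """Zero-noise planted probes satisfy the downstream calling rule."""
        spec, ann, probes = self._setup()
        planted = [self._plant_one(ann, probes, effect=1.5)]
        track, _ = sd.simulate_methylation_arrays(
            probes, planted, noise_sd=0.0, samples=SAMPLES, seed=1
        )
        raw = np.log2(track.ip) - np.log2(track.input_)
        diff = raw[:, SAMPLES.index("d7")] - raw[:, SAMPLES.index("d1")]
        p = planted[0]
        inside = (
            (track.probes["chrom"] == p.chrom)
            & (track.probes["start"] <= p.end)
            & (track.probes["end"] >= p.start)
        ).to_numpy()
        assert inside.sum() == p.n_probes >= 3
        assert (diff[inside] >= 1.0).all()

    def test_placement_error(self):
        spec, ann, probes = self._setup()
        bad = sd.PlantedDMR(
            gene_id="T0001", chrom="chr9", start=1, end=400, direction="gain",
            effect_size=1.5, n_probes=4, contrast=("d1", "d7"),
        )
        with pytest.raises(PlacementError):
            sd.simulate_methylation_arrays(
                probes, [bad], noise_sd=0.0, samples=SAMPLES, seed=1
            )

    def test_determinism(self):
        spec, ann, probes = self._setup()
        a, _ = sd.simulate_methylation_arrays(
            probes, [], noise_sd=0.3, samples=SAMPLES, seed=5
        )
        b, _ = sd.simulate_methylation_arrays(
            probes, [], noise_sd=0.3, samples=SAMPLES, seed=5
        )
        np.testing.assert_array_equal(a.ip, b.ip)
        np.testing.assert_array_equal(a.input_, b.input_)

    def test_planted_dataclass_invariants(self):
        with pytest.raises(ValidationError):
            sd.PlantedDMR("g", "chr1", 1, 2, "gain", 1.5, 2, ("a", "b"))
        with pytest.raises(ValidationError):
            sd.PlantedDMR("g", "chr1", 1, 2, "gain", -1.0, 3, ("a", "b"))


class TestPlantDmrs:
    def test_counts_and_retained_structure(self):
        spec = small_spec(n_genes=30, chrom_length=600_000)
        ann = sd.simulate_annotation(spec)
        probes = sd.tile_probes(ann, spec)
        contrasts = [("d1", "d7"), ("d1", "w2"), ("d1", "w8")]
        planted = sd.plant_dmrs(
            ann, probes, n_dmrs=12, effect_size=1.5, n_probes=4,
            contrasts=contrasts, n_retained=2, seed=1,
        )
        assert len(planted) == 12
        by_region = {}
        for p in planted:
            by_region.setdefault((p.chrom, p.start, p.end), []).append(p)
        retained = [v for v in by_region.values() if len(v) == 3]
        assert len(retained) == 2
        for group in retained:
            assert {p.contrast for p in group} == set(contrasts)
            assert len({p.direction for p in group}) == 1


class TestExpression:
    def _ann(self):
        return sd.simulate_annotation(small_spec(n_genes=5, seed=2))

    def test_zero_noise_exact_fold_change(self):
        ann = self._ann()
        tid = ann.transcripts["transcript_id"].iloc[0]
        planted = [sd.PlantedExpressionChange(tid, 1.0, ("d1", "d7"))]
        table, truth = sd.simulate_expression(
            ann, planted, noise_sd=0.0, samples=SAMPLES,
            n_probes_per_transcript=3, seed=3,
        )
        sub = table[table["transcript_id"] == tid]
        mat = np.log2(
            sub.pivot_table(index="probe_id", columns="sample", values="signal")[
                SAMPLES
            ].to_numpy()
        )
        expr = rma_summarize(mat)
        assert expr[SAMPLES.index("d7")] - expr[SAMPLES.index("d1")] == pytest.approx(
            1.0, abs=1e-9
        )
        assert len(truth) == 1

    def test_empty_planted_all_zero_differences(self):
        ann = self._ann()
        table, truth = sd.simulate_expression(
            ann, [], noise_sd=0.0, samples=SAMPLES,
            n_probes_per_transcript=3, seed=3,
        )
        for tid, sub in table.groupby("transcript_id"):
            mat = np.log2(
                sub.pivot_table(index="probe_id", columns="sample", values="signal")[
                    SAMPLES
                ].to_numpy()
            )
            expr = rma_summarize(mat)
            np.testing.assert_allclose(expr - expr[0], 0.0, atol=1e-9)
        assert truth.empty

    def test_determinism(self):
        ann = self._ann()
        a, _ = sd.simulate_expression(
            ann, [], noise_sd=0.2, samples=SAMPLES,
            n_probes_per_transcript=3, seed=4,
        )
        b, _ = sd.simulate_expression(
            ann, [], noise_sd=0.2, samples=SAMPLES,
            n_probes_per_transcript=3, seed=4,
        )
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_transcript_rejected(self):
        ann = self._ann()
        with pytest.raises(UnknownReferenceError):
            sd.simulate_expression(
                ann,
                [sd.PlantedExpressionChange("NOPE", 1.0, ("d1", "d7"))],
                noise_sd=0.0, samples=SAMPLES, n_probes_per_transcript=3, seed=1,
            )

    def test_bad_probe_count_rejected(self):
        with pytest.raises(ValidationError):
            sd.simulate_expression(
                self._ann(), [], noise_sd=0.0, samples=SAMPLES,
                n_probes_per_transcript=0, seed=1,
            )


class TestCqSimulation:
    def test_levels_roundtrip_at_zero_noise(self):
        from medipchip.qpcr_validation import expression_table, methylation_table

        meth, expr = sd.simulate_cq_tables(
            {"d1": 0.3, "d7": 0.6}, {"d1": 1.0, "d7": 0.4},
            n_individuals=3, n_replicates=2, cq_sd=0.0, seed=1,
        )
        got_m = methylation_table(meth).groupby("timepoint")["level"].mean()
        assert got_m["d1"] == pytest.approx(0.3, abs=1e-9)
        assert got_m["d7"] == pytest.approx(0.6, abs=1e-9)
        got_e = expression_table(expr).groupby("timepoint")["level"].mean()
        assert got_e["d1"] == pytest.approx(1.0, abs=1e-9)
        assert got_e["d7"] == pytest.approx(0.4, abs=1e-9)
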