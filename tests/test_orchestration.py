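"""End-to-end simulation: non-overlap, generation order, modes, parallelism."""

import numpy as np
import pytest
from scipy import stats

from svforge import (
    CSV_IDS,
    GENERATION_ORDER,
    ExactVariantRow,
    SimulationConfig,
    run_mode,
    run_parallel,
    simulate,
)
from svforge.fixtures import make_reference, make_tr_bed, telomere_biased_probs
from svforge.distribution_learning import SpatialProfile, partition_bins


def type_key(rec):
    if rec.is_composite:
        return rec.csv_type
    return "TRA" if rec.vtype.startswith("TRA") else rec.vtype


def all_reserved_intervals(variants):
    out = []
    for rec in variants:
        for iv in rec.reserved_intervals():
            out.append((iv, type_key(rec)))
    return out


class TestNonOverlapAndOrder:
    @pytest.mark.parametrize("seed", range(10))
    def test_fuzz_disjoint_and_ordered(self, seed, toy_reference, mixed_config):
        cfg = SimulationConfig(**{**mixed_config.__dict__, "seed": seed})
        res = simulate(cfg, toy_reference)
        tagged = all_reserved_intervals(res.variants)
        ivs = sorted(iv for iv, _ in tagged)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            assert b1 <= a2, "reserved intervals must be pairwise disjoint"
        # merged list respects the fixed generation order
        order = [GENERATION_ORDER.index(type_key(r)) for r in res.variants]
        assert order == sorted(order)

    def test_snp_never_inside_earlier_footprint(self, toy_reference):
        cfg = SimulationConfig(
            mode="uniform", counts={"DEL": 30, "SNP": 200},
            sv_length_range=(50, 100), seed=3,
        )
        res = simulate(cfg, toy_reference)
        del_ivs = [(r.start, r.end) for r in res.variants if r.vtype == "DEL"]
        for rec in res.variants:
            if rec.vtype != "SNP":
                continue
            assert not any(a <= rec.start < b for a, b in del_ivs)

    def test_blocked_regions_and_n_runs_excluded(self):
        ref = make_reference(10_000, seed=1, n_run_spec=[(2000, 2500)])
        cfg = SimulationConfig(
            mode="uniform", counts={"SNP": 300}, seed=2,
            blocked_regions=[(5000, 6000)],
        )
        res = simulate(cfg, ref)
        for rec in res.variants:
            assert not 2000 <= rec.start < 2500
            assert not 5000 <= rec.start < 6000

    def test_unsatisfiable_density_skips_and_completes(self):
        ref = make_reference(2_000, seed=1)
        cfg = SimulationConfig(
            mode="uniform", counts={"DEL": 100}, sv_length_range=(500, 500),
            seed=1, retry_cap=20,
        )
        res = simulate(cfg, ref)  # must terminate
        assert res.realized_counts.get("DEL", 0) < 100
        assert res.skipped_counts.get("DEL", 0) > 0
        assert res.realized_counts.get("DEL", 0) + res.skipped_counts["DEL"] == 100


class TestModes:
    def test_uniform_mode_uniformity(self):
        """2,000 deletions across 500 kb bins pass a chi-square uniformity
        test on a 1 Mb reference."""
        ref = make_reference(1_000_000, seed=21)
        cfg = SimulationConfig(
            mode="uniform", counts={"DEL": 2000}, sv_length_range=(50, 60),
            seed=5,
        )
        res = simulate(cfg, ref)
        starts = [r.start for r in res.variants]
        counts = np.histogram(starts, bins=[0, 500_000, 1_000_000])[0]
        assert counts.sum() == 2000
        assert stats.chisquare(counts).pvalue > 0.01

    def test_exact_mode_places_at_given_positions(self, tmp_path):
        ref = make_reference(10_000, seed=22)
        rows = [
            ExactVariantRow(position=1001, vtype="DEL", length=100),
            ExactVariantRow(position=4001, vtype="INV", length=200),
            ExactVariantRow(position=7001, vtype="INS", length=60),
        ]
        cfg = SimulationConfig(mode="exact", seed=0, het_prob=0.0)
        res = run_mode(cfg, ref, exact_rows=rows)
        assert [(r.vtype, r.start) for r in res.variants] == [
            ("DEL", 1000), ("INV", 4000), ("INS", 7000),
        ]

    def test_exact_mode_rejects_overlapping_rows(self):
        ref = make_reference(10_000, seed=23)
        rows = [
            ExactVariantRow(position=1001, vtype="DEL", length=100),
            ExactVariantRow(position=1050, vtype="INV", length=100),
        ]
        from svforge.genome_io import ExactTableError

        with pytest.raises(ExactTableError, match="overlap"):
            run_mode(SimulationConfig(mode="exact"), ref, exact_rows=rows)

    def test_exact_mode_csv_group_forms_composite(self):
        ref = make_reference(10_000, seed=24)
        rows = [
            ExactVariantRow(position=1001, vtype="DEL", length=100, csv_group="g1"),
            ExactVariantRow(position=1201, vtype="INV", length=100, csv_group="g1"),
        ]
        res = run_mode(SimulationConfig(mode="exact"), ref, exact_rows=rows)
        assert len(res.variants) == 1
        assert res.variants[0].is_composite
        assert [c.csv_index for c in res.variants[0].components] == [1, 2]

    def test_wave_mode_follows_learned_profile(self, tmp_path):
        """Variants learned from a biased cohort concentrate where the
        cohort did."""
        from svforge.fixtures import make_cohort

        G, L = 2_000_000, 500_000
        ref = make_reference(G, seed=25)
        truth = np.array([0.7, 0.1, 0.1, 0.1])
        paths, _ = make_cohort(
            n_samples=1, profile_truth=truth, seed=7, reference_length=G,
            bin_size=L, mean_count=2000, out_dir=tmp_path,
            length_mixture=((80, 1.0),),
        )
        cfg = SimulationConfig(
            mode="wave", counts={"DEL": 1000}, bin_size=L, seed=8,
        )
        res = run_mode(cfg, ref, bed_paths=paths, sample_ids=["s1"])
        starts = [r.start for r in res.variants if r.vtype == "DEL"]
        frac_bin1 = np.mean([s < L for s in starts])
        assert abs(frac_bin1 - 0.7) < 0.08

    def test_wave_region_tr_enrichment(self):
        """TR weight 0.9 on a 10%-coverage TR set puts >= 70% of placements
        inside TR regions."""
        ref = make_reference(1_000_000, seed=26)
        tr = make_tr_bed(ref, 0.10, seed=5)
        prof = SpatialProfile(
            vtype="DEL", counts=np.array([1.0, 1.0]),
            probs=np.array([0.5, 0.5]), n_samples=1,
        )
        cfg = SimulationConfig(
            mode="wave_region", counts={"DEL": 1000}, seed=9,
            tr_weights=(0.9, 0.1), sv_length_range=(50, 60),
        )
        res = run_mode(cfg, ref, profiles={"DEL": prof}, tr_regions=tr)
        starts = [r.start for r in res.variants]
        ivs = sorted(tr)
        in_tr = sum(any(a <= s < b for a, b in ivs) for s in starts)
        assert in_tr / len(starts) >= 0.70

    def test_vcf_filter_mode_writes_exact_table(self, tmp_path):
        vcf = tmp_path / "pop.vcf"
        vcf.write_text(
            '##fileformat=VCFv4.3\n'
            '##contig=<ID=chr21,length=100000>\n'
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="t">\n'
            '##INFO=<ID=AF_fin,Number=1,Type=Float,Description="t">\n'
            '#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n'
            'chr21\t500\ts1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-100;AF_fin=0.01\n'
        )
        cfg = SimulationConfig(mode="vcf_filter")
        res = run_mode(cfg, vcf_path=vcf, vcf_expression="AF_fin > 0.001",
                       out_prefix=tmp_path / "flt")
        assert len(res.exact_rows) == 1
        assert res.paths["exact_table"].exists()

    def test_missing_mode_input_names_the_flag(self):
        ref = make_reference(1000, seed=1)
        with pytest.raises(ValueError, match="BED"):
            run_mode(SimulationConfig(mode="wave"), ref)

    def test_rates_convert_to_totals(self):
        ref = make_reference(100_000, seed=27)
        cfg = SimulationConfig(mode="uniform", rates={"SNP": 1e-3}, seed=1)
        res = simulate(cfg, ref)
        assert res.realized_counts["SNP"] == 100

    def test_uniform_equals_wave_with_flat_profile(self):
        """Uniform mode is distributionally the same as wave mode driven by
        a flat spatial profile (chi-square on pooled bin counts)."""
        G, L = 1_000_000, 100_000
        part = partition_bins(G, L)
        flat = SpatialProfile(
            vtype="DEL", counts=part.widths().astype(float),
            probs=part.widths() / part.widths().sum(), n_samples=1,
        )
        uni_counts = np.zeros(part.M)
        wave_counts = np.zeros(part.M)
        for seed in range(20):
            ref = make_reference(G, seed=30)
            cfg_u = SimulationConfig(
                mode="uniform", counts={"DEL": 200}, bin_size=L,
                sv_length_range=(50, 60), seed=seed,
            )
            cfg_w = SimulationConfig(
                mode="wave", counts={"DEL": 200}, bin_size=L,
                sv_length_range=(50, 60), seed=seed + 1000,
            )
            for cfg, acc, profs in (
                (cfg_u, uni_counts, None),
                (cfg_w, wave_counts, {"DEL": flat}),
            ):
                res = simulate(cfg, ref, profiles=profs)
                for r in res.variants:
                    acc[min(r.start // L, part.M - 1)] += 1
        # two independent samples: homogeneity test on the 2 x M table
        chi2, p, _, _ = stats.chi2_contingency(np.vstack([uni_counts, wave_counts]))
        assert p > 0.01


class TestParallelContract:
    def test_serial_equals_parallel(self):
        ref = make_reference(400_000, seed=31)
        def run(cores):
            cfg = SimulationConfig(
                mode="uniform_parallel", counts={"DEL": 50, "SNP": 100},
                bin_size=50_000, segments=4, cores=cores, seed=17,
                sv_length_range=(50, 80),
            )
            return run_parallel(cfg, ref)
        r1, r4 = run(1), run(4)
        key = lambda r: [(v.vtype, v.start, v.end, v.payload, v.genotype)
                         for v in r.variants]
        assert key(r1) == key(r4)
        assert r1.donors == r4.donors

    def test_no_variant_spans_a_segment_boundary(self):
        ref = make_reference(400_000, seed=32)
        cfg = SimulationConfig(
            mode="uniform_parallel", counts={"DEL": 200}, bin_size=50_000,
            segments=4, seed=18, sv_length_range=(50, 80),
        )
        res = run_parallel(cfg, ref)
        boundaries = [100_000, 200_000, 300_000]
        for rec in res.variants:
            for b in boundaries:
                assert not (rec.start < b < rec.end)

    def test_total_realized_is_sum_of_segments(self):
        ref = make_reference(400_000, seed=33)
        cfg = SimulationConfig(
            mode="uniform_parallel", counts={"DEL": 120}, bin_size=50_000,
            segments=4, seed=19, sv_length_range=(50, 80),
        )
        res = run_parallel(cfg, ref)
        assert res.realized_counts["DEL"] + res.skipped_counts.get("DEL", 0) == 120

    def test_segment_smaller_than_largest_variant_errors(self):
        ref = make_reference(10_000, seed=34)
        cfg = SimulationConfig(
            mode="uniform_parallel", counts={"DEL": 1}, bin_size=1000,
            segments=10, seed=1, sv_length_range=(50, 5000),
        )
        with pytest.raises(ValueError, match="segment"):
            run_parallel(cfg, ref)


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path, toy_reference, mixed_config):
        files = []
        for sub in ("a", "b"):
            res = run_mode(mixed_config, toy_reference,
                           out_prefix=tmp_path / sub / "run")
            files.append({k: p.read_bytes() for k, p in res.paths.items()})
        assert files[0] == files[1]
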