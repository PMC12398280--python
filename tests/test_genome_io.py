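"""Reference/BED/exact-table I/O, population-VCF filtering, output emission."""

import numpy as np
import pysam
import pytest

from svforge import (
    ExactVariantRow,
    PopulationFilterExpression,
    ReferenceSequence,
    SimulationConfig,
    emit_outputs,
    filter_population_vcf,
    read_bed_variants,
    read_fasta,
    run_mode,
    simulate,
    validate_exact_table,
)
from svforge.genome_io import BedRowError, ExactTableError, FastaFormatError
from svforge.fixtures import make_reference


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].name == "chr" and recs[0].length == 4

    def test_multi_record_order_preserved(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">a\nACGT\n>b\nGGCC\n")
        recs = read_fasta(p)
        assert [r.name for r in recs] == ["a", "b"]

    def test_lowercase_normalised(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr\nacgt\n")
        assert read_fasta(p)[0].bases == "ACGT"

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr\nACRYGT\n")
        assert read_fasta(p)[0].bases == "ACNNGT"

    def test_non_iupac_residue_rejected(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">chr\nACZT\n")
        with pytest.raises(FastaFormatError, match="chr"):
            read_fasta(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "absent.fa")


class TestReadBedVariants:
    def test_deletion_row_arithmetic(self, tmp_path):
        p = tmp_path / "s1.bed"
        p.write_text("chr21\t100\t300\tDEL\n")
        obs = read_bed_variants([p], ["s1"])
        assert obs[0].vtype == "DEL" and obs[0].length == 200
        assert obs[0].start == 100 and obs[0].end == 300

    def test_sample_tags_distinct(self, tmp_path):
        p1 = tmp_path / "a.bed"
        p2 = tmp_path / "b.bed"
        p1.write_text("chr21\t0\t100\tDEL\n")
        p2.write_text("chr21\t0\t100\tDEL\n")
        obs = read_bed_variants([p1, p2], ["s1", "s2"])
        assert {o.sample_id for o in obs} == {"s1", "s2"}

    def test_inverted_interval_errors_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr21\t300\t100\tDEL\n")
        with pytest.raises(BedRowError, match="line 1"):
            read_bed_variants([p], ["s1"])

    def test_unknown_type_strict_vs_lenient(self, tmp_path):
        p = tmp_path / "odd.bed"
        p.write_text("chr21\t0\t100\tDEL\nchr21\t200\t300\tWEIRD\n")
        with pytest.raises(BedRowError, match="WEIRD"):
            read_bed_variants([p], ["s1"])
        obs = read_bed_variants([p], ["s1"], strict=False)
        assert len(obs) == 1

    def test_insertion_length_from_fifth_column(self, tmp_path):
        p = tmp_path / "ins.bed"
        p.write_text("chr21\t500\t501\tINS\t180\n")
        obs = read_bed_variants([p], ["s1"])
        assert obs[0].length == 180 and obs[0].end == obs[0].start == 500


class TestValidateExactTable:
    @pytest.fixture
    def ref1k(self):
        return make_reference(1000, seed=5)

    def test_deletion_row_passes(self, ref1k):
        rows = [ExactVariantRow(position=100, vtype="DEL", length=50)]
        assert validate_exact_table(rows, ref1k) == rows

    def test_balanced_tra_requires_both_regions(self, ref1k):
        rows = [ExactVariantRow(position=100, vtype="TRA", length=50)]
        with pytest.raises(ExactTableError, match="missing exchanged region"):
            validate_exact_table(rows, ref1k)

    def test_dup_requires_destination(self, ref1k):
        rows = [ExactVariantRow(
            position=100, vtype="DUP", length=50,
            source_start=100, source_end=150,
        )]
        with pytest.raises(ExactTableError, match="missing destination"):
            validate_exact_table(rows, ref1k)

    def test_position_beyond_reference_rejected(self, ref1k):
        rows = [ExactVariantRow(position=5000, vtype="DEL", length=50)]
        with pytest.raises(ExactTableError, match="outside"):
            validate_exact_table(rows, ref1k)


TOY_VCF = """##fileformat=VCFv4.3
##contig=<ID=chr21,length=100000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=AF_fin,Number=1,Type=Float,Description="Finnish AF">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr21\t1000\tsv1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-200;END=1200;AF_fin=0.0005
chr21\t5000\tsv2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-300;END=5300;AF_fin=0.002
chr21\t9000\tsv3\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=500;END=9000;AF_fin=0.01
"""


class TestFilterPopulationVcf:
    @pytest.fixture
    def toy_vcf(self, tmp_path):
        p = tmp_path / "pop.vcf"
        p.write_text(TOY_VCF)
        return p

    def test_threshold_keeps_two(self, toy_vcf):
        rows = filter_population_vcf(toy_vcf, "AF_fin > 0.001")
        assert len(rows) == 2
        assert [r.position for r in rows] == [5000, 9000]
        assert [r.vtype for r in rows] == ["DEL", "INS"]
        assert rows[0].length == 300

    def test_empty_result_no_error(self, toy_vcf):
        assert filter_population_vcf(toy_vcf, "AF_fin > 0.5") == []

    def test_conjunction(self, toy_vcf):
        rows = filter_population_vcf(toy_vcf, "AF_fin > 0.001 AND AF_fin < 0.005")
        assert len(rows) == 1 and rows[0].position == 5000

    def test_overlapping_survivors_keep_first(self, tmp_path):
        text = TOY_VCF.replace(
            "chr21\t5000\tsv2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-300;END=5300;AF_fin=0.002",
            "chr21\t5000\tsv2\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-300;END=5300;AF_fin=0.002\n"
            "chr21\t5300\tsv2b\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-100;END=5400;AF_fin=0.002",
        )
        p = tmp_path / "pop2.vcf"
        p.write_text(text)
        rows = filter_population_vcf(p, "AF_fin > 0.001")
        # sv2 spans [4999,5300); sv2b starts inside it (1-bp overlap) and drops
        assert [r.position for r in rows] == [5000, 9000]

    def test_unknown_info_key_is_header_error(self, toy_vcf):
        with pytest.raises(ValueError, match="AF_xyz"):
            filter_population_vcf(toy_vcf, "AF_xyz > 0.001")

    def test_unparsable_clause(self):
        with pytest.raises(ValueError, match="parse"):
            PopulationFilterExpression.parse("AF_fin >> 0.001")

    def test_output_is_valid_exact_table(self, toy_vcf):
        ref = make_reference(100_000, seed=1)
        rows = filter_population_vcf(toy_vcf, "AF_fin > 0.001")
        assert validate_exact_table(rows, ref) == rows


class TestEmitOutputs:
    def test_empty_variant_set_identity(self, tmp_path):
        ref = make_reference(500, seed=9)
        from svforge.variant_constructors import CoordinateMap

        cmap = CoordinateMap(ploidy=1, positions=[{}], donor_lengths=[500])
        paths = emit_outputs(ref, [], [ref.bases], cmap, tmp_path / "out")
        fasta = paths["fasta"].read_text()
        assert "".join(fasta.splitlines()[1:]) == ref.bases
        vcf_lines = paths["vcf"].read_text().splitlines()
        assert vcf_lines[0] == "##fileformat=VCFv4.3"
        assert all(l.startswith("#") for l in vcf_lines)

    def test_vcf_parses_and_sv_conventions_hold(self, tmp_path):
        ref = make_reference(20_000, seed=10)
        cfg = SimulationConfig(
            mode="uniform",
            counts={"DEL": 3, "INS": 2, "INV": 2, "DUP": 1, "TRA": 1,
                    "SMALL_DEL": 3, "SMALL_INS": 3, "SNP": 5},
            csv_counts={"ID4": 1},
            sv_length_range=(50, 150), seed=4,
        )
        res = simulate(cfg, ref)
        paths = emit_outputs(ref, res.variants, res.donors,
                             res.coordinate_map, tmp_path / "run")
        vcf = pysam.VariantFile(str(paths["vcf"]))
        assert "CSV-TYPE" in vcf.header.info and "CSV-INDEX" in vcf.header.info
        n = 0
        for rec in vcf:
            n += 1
            assert 1 <= rec.pos <= ref.length
            svtype = rec.info.get("SVTYPE")
            if svtype == "DEL" and rec.alts == ("<DEL>",):
                svlen = rec.info["SVLEN"]
                assert svlen < 0
                # pysam exposes END via record.stop (0-based exclusive ==
                # the 1-based inclusive END printed in the file)
                assert rec.stop == rec.pos + abs(svlen)
        assert n > 0

    def test_composite_components_share_csv_type(self, tmp_path):
        ref = make_reference(20_000, seed=12)
        cfg = SimulationConfig(mode="csv", csv_counts={"ID4": 1}, seed=1,
                               csv_length_range=(50, 100))
        res = simulate(cfg, ref)
        paths = emit_outputs(ref, res.variants, res.donors,
                             res.coordinate_map, tmp_path / "csvrun")
        vcf = pysam.VariantFile(str(paths["vcf"]))
        tagged = [(r.info["CSV-TYPE"], r.info["CSV-INDEX"])
                  for r in vcf if "CSV-TYPE" in r.info]
        assert {t for t, _ in tagged} == {"ID4"}
        assert sorted(i for _, i in tagged) == [1, 2]

    def test_bed_to_truth_round_trip_no_off_by_one(self, tmp_path):
        """A 0-based half-open BED deletion re-emerges in the truth table with
        identical coordinates, and in the VCF 1-based with END = POS + len."""
        import pandas as pd

        ref = make_reference(5_000, seed=13)
        bed = tmp_path / "s1.bed"
        bed.write_text("chrSim\t100\t300\tDEL\n")
        obs = read_bed_variants([bed], ["s1"])
        row = ExactVariantRow(position=obs[0].start + 1, vtype="DEL",
                              length=obs[0].length)
        cfg = SimulationConfig(mode="exact", seed=0, het_prob=0.0)
        res = run_mode(cfg, ref, exact_rows=[row], out_prefix=tmp_path / "rt")
        truth = pd.read_csv(res.paths["truth"], sep="\t")
        assert int(truth.loc[0, "ref_start"]) == 100
        assert int(truth.loc[0, "ref_end"]) == 300
        vcf = pysam.VariantFile(str(res.paths["vcf"]))
        rec = next(iter(vcf))
        assert rec.pos == 100  # anchor base before the deleted run
        assert rec.stop == 300
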