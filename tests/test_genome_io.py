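import pytest
from hypothesis import given, settings, strategies as st

from varcohort import datasets
from varcohort.genome_io import (
    FormatError,
    GenomeIndex,
    build_coverage_track,
    read_coverage,
    read_genome_index,
    read_vcf_result,
    write_vcf,
)
from varcohort.variant_model import VariantCall


class TestGenomeIndex:
    def test_reads_fai_dialect_in_file_order(self, tmp_path):
        path = tmp_path / "toy.fa.fai"
        path.write_text("chrB\t1000\t10\t60\t61\nchrA\t500\t1100\t60\t61\n")
        genome = read_genome_index(path)
        assert genome.names == ("chrB", "chrA")
        assert genome.total_length == 1500

    def test_single_chromosome(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("chr1\t1000\n")
        assert read_genome_index(path).total_length == 1000

    def test_bundled_rice_index_sums_to_reference_length(self):
        genome = datasets.rice_genome_index()
        assert len(genome.chromosomes) == 12
        assert genome.total_length == 373_245_519

    def test_duplicate_and_nonpositive_rejected(self, tmp_path):
        dup = tmp_path / "dup.tsv"
        dup.write_text("chr1\t100\nchr1\t200\n")
        with pytest.raises(FormatError):
            read_genome_index(dup)
        neg = tmp_path / "neg.tsv"
        neg.write_text("chr1\t0\n")
        with pytest.raises(FormatError):
            read_genome_index(neg)

    def test_centromere_must_lie_on_chromosome(self):
        with pytest.raises(FormatError):
            GenomeIndex(
                chromosomes=(("chr1", 100),), centromere_mid={"chr1": 200}
            )


class TestCoverage:
    def test_full_coverage(self, tmp_path, toy_genome):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t1000\t5\n")
        assert read_coverage(path, toy_genome).covered_length == 1000

    def test_partial_coverage_and_depth_lookup(self, tmp_path, toy_genome):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t400\t4\nchr1\t600\t1000\t1\n")
        track = read_coverage(path, toy_genome, "L")
        assert track.covered_length == 800
        assert track.depth_at("chr1", 400) == 4  # 1-based: last base of [0,400)
        assert track.depth_at("chr1", 500) == 0
        assert track.min_depth("chr1", 1, 400) == 4
        assert track.min_depth("chr1", 399, 402) == 0  # spans the gap

    def test_zero_depth_rows_not_counted_as_covered(self, toy_genome):
        track = build_coverage_track(
            "L", [("chr1", 0, 100, 0), ("chr1", 100, 1000, 9)], toy_genome
        )
        assert track.covered_length == 900
        assert track.depth_at("chr1", 50) == 0

    def test_bounds_and_overlap_errors(self, tmp_path, toy_genome):
        beyond = tmp_path / "a.bedgraph"
        beyond.write_text("chr1\t0\t2000\t3\n")
        with pytest.raises(FormatError):
            read_coverage(beyond, toy_genome)
        overlap = tmp_path / "b.bedgraph"
        overlap.write_text("chr1\t0\t500\t3\nchr1\t400\t600\t2\n")
        with pytest.raises(FormatError):
            read_coverage(overlap, toy_genome)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(split=st.integers(min_value=1, max_value=399))
    def test_covered_length_invariant_under_interval_splitting(self, split):
        genome = GenomeIndex(chromosomes=(("chr1", 1000),))
        whole = build_coverage_track("L", [("chr1", 0, 400, 7)], genome)
        parts = build_coverage_track(
            "L",
            [("chr1", 0, split, 7), ("chr1", split, 400, 7)],
            genome,
        )
        assert whole.covered_length == parts.covered_length == 400


class TestVcf:
    def test_round_trip_identity(self, tmp_path, toy_genome):
        calls = [
            VariantCall.make("L", "chr1", 100, "A", "G", 45.0, 30),
            VariantCall.make("L", "chr1", 200, "AT", "A", 60.5, 12),
            VariantCall.make("L", "chr2", 5, "C", "CGG", 31.2, 99),
        ]
        path = tmp_path / "L.vcf"
        write_vcf(calls, path, toy_genome)
        back = read_vcf_result(path, "L", toy_genome).calls
        assert [(c.chrom, c.pos, c.ref, c.alt, c.site_depth) for c in back] == [
            (c.chrom, c.pos, c.ref, c.alt, c.site_depth) for c in calls
        ]
        for a, b in zip(back, calls):
            assert a.quality == pytest.approx(b.quality, rel=1e-5)

    def test_multiallelic_split_and_rejections(self, tmp_path, toy_genome):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tG,T\t50\t.\tDP=40\n"
            "chr1\t150\t.\tA\tC\t.\t.\tDP=12\n"  # missing QUAL
            "chr1\t200\t.\tAC\tGT\t60\t.\tDP=33\n"  # complex
        )
        res = read_vcf_result(path, "L", toy_genome)
        assert [(c.pos, c.alt) for c in res.calls] == [(100, "G"), (100, "T")]
        assert res.n_missing_qual == 1
        assert res.n_complex == 1

    def test_unknown_chromosome_names_the_record(self, tmp_path, toy_genome):
        path = tmp_path / "u.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chrZ,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chrZ\t10\t.\tA\tG\t50\t.\t.\n"
        )
        with pytest.raises(FormatError, match="chrZ"):
            read_vcf_result(path, "L", toy_genome)
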