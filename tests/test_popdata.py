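"""Genotype/survey I/O, locus filtering, and the RAD read-QC rule."""

import numpy as np
import pytest

import atollpop as ap
from atollpop.popdata import ParseError, EmptyInputError, quality_product

from conftest import fastq_record, make_matrix, random_matrix

MISSING = ap.MISSING

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=c1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
c1\t10\tsnp1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1
c1\t20\tsnp2\tA\tC\t.\tPASS\t.\tGT\t./.\t1/1
c1\t30\tmulti\tA\tC,G\t.\tPASS\t.\tGT\t0/1\t0/2
"""

GENEPOP_TEXT = """\
two-sample fixture
locA
locB
POP
s1 , 0101 0102
s2 , 0102 0000
"""


class TestReadGenotypes:
    def test_vcf_codes_missing_and_multiallelic_skip(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_TEXT)
        g = ap.read_genotypes(path, "vcf")
        assert g.individuals == ["s1", "s2"]
        # multi-allelic record skipped; 0/0 -> 0, 0/1 -> 1, ./. -> MISSING
        assert g.n_loci == 2
        assert g.calls.tolist() == [[0, MISSING], [1, 2]]
        assert g.loci[0].ref == "A" and g.loci[0].alt == "C"

    def test_genepop_two_digit_minor_is_alt(self, tmp_path):
        # hand parse: locA alleles 01,01,01,02 -> minor 02 is alt -> codes 0,1
        path = tmp_path / "t.gen"
        path.write_text(GENEPOP_TEXT)
        g = ap.read_genotypes(path, "genepop")
        assert g.individuals == ["s1", "s2"]
        a = [m.id for m in g.loci].index("locA")
        b = [m.id for m in g.loci].index("locB")
        assert g.loci[a].alt == "02"
        assert g.calls[:, a].tolist() == [0, 1]
        assert g.calls[:, b].tolist() == [1, MISSING]  # 0000 is missing

    def test_malformed_genepop_names_line(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("title\nlocA\nPOP\ns1 , 0101 0102\n")
        with pytest.raises(ParseError, match="line 4"):
            ap.read_genotypes(path, "genepop")

    def test_empty_vcf_sample_list_rejected(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(EmptyInputError):
            ap.read_genotypes(path, "vcf")

    @pytest.mark.parametrize("fmt", ["vcf", "csv"])
    def test_round_trip_exact(self, tmp_path, rng, fmt):
        g = random_matrix(rng, n=7, L=15)
        path = tmp_path / f"rt.{fmt}"
        ap.write_genotypes(g, path, fmt)
        g2 = ap.read_genotypes(path, fmt)
        assert g2.individuals == g.individuals
        assert [m.id for m in g2.loci] == [m.id for m in g.loci]
        np.testing.assert_array_equal(g2.calls, g.calls)

    def test_genepop_round_trip(self, tmp_path, rng):
        """Genepop does not record which allele is 'alternate', so calls
        round-trip exactly whenever alt is the minor allele, and up to the
        allele-symmetric flip 2-c otherwise."""
        calls = rng.integers(0, 3, size=(9, 10)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        g = make_matrix(calls)
        path = tmp_path / "rt.gen"
        ap.write_genotypes(g, path, "genepop")
        g2 = ap.read_genotypes(path, "genepop")
        assert g2.individuals == g.individuals
        for j in range(g.n_loci):
            a, b = g.calls[:, j], g2.calls[:, j]
            same = np.array_equal(a, b)
            flipped = np.array_equal(np.where(a == MISSING, MISSING, 2 - a), b)
            assert same or flipped
            present = a != MISSING
            if present.any() and a[present].sum() <= present.sum():  # alt minor
                assert same


class TestFilterLoci:
    def test_rare_allele_removed(self):
        # alt count 1 in 24 diploids: freq 1/48 = 0.021 < 0.05
        calls = np.zeros((24, 1), dtype=np.int8)
        calls[0, 0] = 1
        g = make_matrix(calls)
        assert ap.filter_loci(g, maf_min=0.05, completeness_min=0).n_loci == 0

    def test_zero_thresholds_identity(self, rng):
        g = random_matrix(rng, n=10, L=8, missing_rate=0.2)
        g2 = ap.filter_loci(g, maf_min=0.0, completeness_min=0.0)
        np.testing.assert_array_equal(g2.calls, g.calls)

    def test_completeness_cut(self):
        # missing in 6 of 24 -> completeness 0.75 < 0.8 -> removed
        calls = np.tile([[0], [1]], (12, 1)).astype(np.int8)
        calls[:6, 0] = MISSING
        g = make_matrix(calls)
        assert ap.filter_loci(g, maf_min=0.0, completeness_min=0.8).n_loci == 0
        assert ap.filter_loci(g, maf_min=0.0, completeness_min=0.75).n_loci == 1

    def test_idempotent(self, rng):
        g = random_matrix(rng, n=20, L=40, missing_rate=0.15)
        once = ap.filter_loci(g, 0.05, 0.8)
        twice = ap.filter_loci(once, 0.05, 0.8)
        np.testing.assert_array_equal(once.calls, twice.calls)
        assert [m.id for m in once.loci] == [m.id for m in twice.loci]

    def test_all_removed_is_warning_not_error(self):
        g = make_matrix(np.zeros((5, 3), dtype=np.int8))  # all monomorphic
        out = ap.filter_loci(g, maf_min=0.05, completeness_min=0)
        assert out.n_loci == 0 and out.n_individuals == 5


class TestReadQC:
    BARCODES = {"AAAAAA": "fishA", "CCCCCC": "fishB"}

    def test_quality_product_closed_form(self):
        assert quality_product([40] * 92) == pytest.approx((1 - 1e-4) ** 92)
        assert quality_product([10] * 92) == pytest.approx(0.9**92)

    def test_high_quality_read_kept_and_trimmed_to_80(self):
        seq = "AAAAAA" + "TGCAGG" + "ACGT" * 22  # barcode + residue + 88bp
        rec = fastq_record(seq, [40] * len(seq))
        out, rep = ap.demux_and_qc_reads([rec], self.BARCODES)
        assert rep.n_kept == 1 and rep.n_dropped == 0
        (tag,) = out["fishA"]
        assert len(tag) == 80
        assert str(tag.seq) == seq[12:92]

    def test_low_quality_read_dropped(self):
        # 0.9**92 ~ 6.1e-5 < 0.8
        seq = "AAAAAA" + "G" * 94
        rec = fastq_record(seq, [10] * len(seq))
        _, rep = ap.demux_and_qc_reads([rec], self.BARCODES)
        assert rep.n_dropped_quality == 1 and rep.n_kept == 0

    def test_unknown_barcode_unassigned(self):
        seq = "GGGGGG" + "T" * 94
        rec = fastq_record(seq, [40] * len(seq))
        _, rep = ap.demux_and_qc_reads([rec], self.BARCODES)
        assert rep.n_unassigned == 1

    def test_short_read_dropped(self):
        rec = fastq_record("A" * 60, [40] * 60)
        _, rep = ap.demux_and_qc_reads([rec], self.BARCODES)
        assert rep.n_dropped_short == 1

    def test_read_conservation(self, rng):
        reads = []
        for i in range(60):
            length = int(rng.integers(50, 110))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            if i % 3 == 0:  # force some to carry a real barcode
                seq = "AAAAAA" + seq[6:]
            quals = rng.integers(2, 41, size=length).tolist()
            reads.append(fastq_record(seq, quals, read_id=f"r{i}"))
        out, rep = ap.demux_and_qc_reads(reads, self.BARCODES)
        assert rep.n_kept + rep.n_dropped + rep.n_unassigned == rep.n_input == 60
        assert rep.n_kept == sum(len(v) for v in out.values())

    def test_fastq_file_and_json_report(self, tmp_path):
        seq = "CCCCCC" + "TGCAGG" + "A" * 88
        path = tmp_path / "reads.fastq"
        path.write_text(f"@r1\n{seq}\n+\n{'I' * len(seq)}\n")  # 'I' = Q40
        out, rep = ap.demux_and_qc_reads(path, self.BARCODES)
        assert rep.per_sample == {"fishA": 0, "fishB": 1}
        assert '"n_kept": 1' in rep.to_json()

    def test_barcode_collision_rejected(self):
        with pytest.raises(ValueError, match="same sample"):
            ap.demux_and_qc_reads([], {"AAAAAA": "x", "CCCCCC": "x"})


class TestSurveyCSV:
    HEADER = "site,year,stratum,transect_area_m2,species,count\n"

    def test_single_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(self.HEADER + "NC11,2010,shallow,250,H. limbaughi,4\n")
        t = ap.read_survey_csv(p)
        assert len(t) == 1
        assert t.df.loc[0, "count"] == 4
        assert t.years == [2010]

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(self.HEADER)
        assert len(ap.read_survey_csv(p)) == 0

    def test_unknown_stratum_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(self.HEADER + "NC11,2010,mid,250,H. limbaughi,4\n")
        with pytest.raises(ParseError, match="row 1.*mid"):
            ap.read_survey_csv(p)

    def test_negative_count_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            self.HEADER
            + "NC11,2010,shallow,250,sp,4\nNC12,2010,deep,250,sp,-1\n"
        )
        with pytest.raises(ParseError, match="row 2"):
            ap.read_survey_csv(p)
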