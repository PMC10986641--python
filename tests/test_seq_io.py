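import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhcforge import seq_io


class TestFasta:
    def test_basic_record(self):
        recs = seq_io.parse_fasta(io.StringIO(">a\nACGT\n"))
        assert len(recs) == 1
        assert (recs[0].id, recs[0].residues) == ("a", "ACGT")

    def test_description_case_and_line_folding(self):
        recs = seq_io.parse_fasta(io.StringIO(">a x\nac\ngt\n"))
        assert recs[0].description == "x"
        assert recs[0].residues == "ACGT"

    def test_duplicate_id_error_names_the_id(self):
        with pytest.raises(ValueError, match="dup1"):
            seq_io.parse_fasta(io.StringIO(">dup1\nAC\n>dup1\nGT\n"))

    def test_empty_stream(self):
        assert seq_io.parse_fasta(io.StringIO("")) == []

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="abcXYZ0123_", min_size=1, max_size=8),
                st.text(alphabet="ACGTN", min_size=1, max_size=200),
            ),
            min_size=1,
            max_size=5,
            unique_by=lambda kv: kv[0],
        )
    )
    def test_write_parse_roundtrip(self, items):
        records = [seq_io.SequenceRecord(rid, "", seq) for rid, seq in items]
        buf = io.StringIO()
        seq_io.write_fasta(records, buf, width=17)
        back = seq_io.parse_fasta(io.StringIO(buf.getvalue()))
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in records]


class TestAlleleDb:
    def make(self, rows, fasta=None):
        msa = "".join(f">{n}\n{s}\n" for n, s in rows)
        fasta = fasta or "".join(
            f">{n}\n{s.replace('-', '').replace('*', '')}\n" for n, s in rows
        )
        return seq_io.parse_allele_db(io.StringIO(fasta), {"A": io.StringIO(msa)})

    def test_full_rows_are_complete(self):
        alleles = self.make([("A*01:01", "ACGTACGT"), ("A*01:02", "ACGTACGA"), ("A*02:01", "ACCTACGT")])
        assert all(a.is_complete for a in alleles)
        assert {a.locus for a in alleles} == {"A"}

    def test_leading_unknown_columns_incomplete(self):
        core = "ACGT" * 100
        alleles = self.make([("A*01:01", "*" * 200 + core[200:]), ("A*02:01", core)])
        incomplete = next(a for a in alleles if a.allele_name == "A*01:01")
        assert not incomplete.is_complete
        assert incomplete.msa_span == (200, 400)

    def test_allele_absent_from_msa_is_incomplete(self, caplog):
        fasta = ">A*01:01\nACGT\n>A*99:99\nACGT\n"
        alleles = seq_io.parse_allele_db(
            io.StringIO(fasta), {"A": io.StringIO(">A*01:01\nACGT\n")}
        )
        novel = next(a for a in alleles if a.allele_name == "A*99:99")
        assert not novel.is_complete

    def test_empty_msa_all_incomplete(self):
        alleles = seq_io.parse_allele_db(io.StringIO(">A*01:01\nACGT\n"), {})
        assert not alleles[0].is_complete


PAF_LINE = "q\t100\t0\t100\t+\tt\t500\t10\t110\t95\t100\t60"


class TestPaf:
    def test_minimal_line(self):
        (rec,) = seq_io.parse_paf(io.StringIO(PAF_LINE + "\n"))
        assert (rec.q_start, rec.q_end, rec.t_start, rec.t_end) == (0, 100, 10, 110)
        assert rec.n_matches == 95 and rec.block_length == 100
        assert rec.identity == pytest.approx(0.95)

    def test_cigar_parsed(self):
        line = "q\t15\t0\t15\t+\tt\t50\t0\t15\t13\t15\t60\tcg:Z:10=2X3="
        (rec,) = seq_io.parse_paf(io.StringIO(line + "\n"), with_cigar=True)
        assert rec.cigar == [(10, "="), (2, "X"), (3, "=")]

    def test_missing_cigar_is_error(self):
        with pytest.raises(ValueError, match="cg:Z"):
            seq_io.parse_paf(io.StringIO(PAF_LINE + "\n"), with_cigar=True)

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            seq_io.parse_paf(io.StringIO(PAF_LINE + "\nbad\tline\n"))

    def test_write_parse_roundtrip(self):
        (rec,) = seq_io.parse_paf(io.StringIO(PAF_LINE + "\n"))
        buf = io.StringIO()
        seq_io.write_paf([rec], buf)
        (back,) = seq_io.parse_paf(io.StringIO(buf.getvalue()))
        assert back == rec


RM_HEADER = "h1\nh2\n\n"


class TestRepeatMasker:
    def test_empty_body(self):
        assert seq_io.parse_repeatmasker_out(io.StringIO(RM_HEADER)) == []

    def test_coordinate_conversion_and_class(self):
        row = "  500 10.0 0.0 0.0 hap1 101 400 (0) + AluY SINE/Alu 1 300 (0) 1\n"
        (feat,) = seq_io.parse_repeatmasker_out(io.StringIO(RM_HEADER + row))
        assert (feat.start, feat.end) == (100, 400)
        assert feat.repeat_class_family == "SINE/Alu"

    def test_c_strand_maps_to_minus(self):
        row = "  500 10.0 0.0 0.0 hap1 1 50 (0) C L1MC LINE/L1 1 50 (0) 1\n"
        (feat,) = seq_io.parse_repeatmasker_out(io.StringIO(RM_HEADER + row))
        assert feat.strand == "-"

    def test_truncated_line_error(self):
        with pytest.raises(ValueError, match="line 4"):
            seq_io.parse_repeatmasker_out(io.StringIO(RM_HEADER + "500 10.0\n"))

    def test_writer_roundtrip(self):
        feats = [
            seq_io.RepeatFeature("hap1", 100, 400, "AluY", "SINE/Alu", "+"),
            seq_io.RepeatFeature("hap1", 600, 900, "L1MC", "LINE/L1", "-"),
        ]
        buf = io.StringIO()
        seq_io.write_repeatmasker_out(feats, buf)
        assert seq_io.parse_repeatmasker_out(io.StringIO(buf.getvalue())) == feats


class _Ann:
    def __init__(self, name, start, end, strand, exons, coding=True):
        self.gene_name, self.seq_id = name, "asm"
        self.start, self.end, self.strand = start, end, strand
        self.exons, self.coding = exons, coding


class TestGff3:
    def test_gene_with_two_exons(self):
        buf = io.StringIO()
        seq_io.write_gff3([_Ann("G1", 10, 100, "+", [(10, 40), (60, 100)])], buf)
        lines = [l for l in buf.getvalue().splitlines() if not l.startswith("#")]
        types = [l.split("\t")[2] for l in lines]
        assert types == ["gene", "mRNA", "exon", "exon", "CDS", "CDS"]

    def test_minus_strand_ascending_coordinates(self):
        buf = io.StringIO()
        seq_io.write_gff3([_Ann("G1", 10, 100, "-", [(10, 40), (60, 100)])], buf)
        exon_lines = [l for l in buf.getvalue().splitlines() if "\texon\t" in l]
        starts = [int(l.split("\t")[3]) for l in exon_lines]
        assert starts == sorted(starts)
        assert all(l.split("\t")[6] == "-" for l in exon_lines)

    def test_empty_is_pragma_only(self):
        buf = io.StringIO()
        seq_io.write_gff3([], buf)
        assert buf.getvalue() == "##gff-version 3\n"

    def test_exon_outside_gene_bounds(self):
        with pytest.raises(ValueError, match="outside gene bounds"):
            seq_io.write_gff3([_Ann("G1", 10, 100, "+", [(5, 40)])], io.StringIO())

    def test_write_parse_roundtrip(self):
        anns = [
            _Ann("G1", 10, 100, "+", [(10, 40), (60, 100)]),
            _Ann("G2", 200, 300, "-", [(200, 300)]),
        ]
        buf = io.StringIO()
        seq_io.write_gff3(anns, buf)
        back = seq_io.parse_gff3(io.StringIO(buf.getvalue()))
        assert [(g.gene_name, g.start, g.end, g.strand, g.exons) for g in back] == [
            (a.gene_name, a.start, a.end, a.strand, a.exons) for a in anns
        ]


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=asm,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
asm\t101\t.\tA\tG\t50\tPASS\t.\tGT\t1/1
asm\t201\t.\tC\tCTT\t50\tPASS\t.\tGT\t0/1
asm\t301\t.\tGAA\tG\t50\tPASS\t.\tGT\t1/1
"""


class TestVcfAndSam:
    def test_vcf_zygosity_and_kinds(self, tmp_path):
        path = tmp_path / "x.vcf"
        path.write_text(VCF_TEXT)
        calls = seq_io.read_variant_calls(str(path))
        assert [(c.pos, c.kind, c.zygosity) for c in calls] == [
            (100, "snp", "hom"),
            (200, "ins", "het"),
            (300, "del", "hom"),
        ]

    def test_sam_flags(self, tmp_path):
        sam = (
            "@HD\tVN:1.6\n@SQ\tSN:mhc\tLN:1000\n"
            "r1\t99\tmhc\t10\t60\t10M\t=\t60\t60\tACGTACGTAC\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
        )
        path = tmp_path / "x.sam"
        path.write_text(sam)
        recs = seq_io.read_sam_alignments(str(path))
        assert recs[0].is_proper_pair and not recs[1].is_proper_pair
        assert recs[0].target_id == "mhc"
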