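import numpy as np
import pysam
import pytest

from capsv import seqio
from capsv.discovery import SVCall
from capsv.junction import JunctionNode
from capsv.seqio import BedParseError, GenomeModel, UngroupedInputError


@pytest.fixture()
def bed(tmp_path):
    p = tmp_path / "targets.bed"
    p.write_text("chr1\t399999\t650000\tlocusA\nchr2\t100\t5100\tlocusB\n")
    return str(p)


class TestTargets:
    def test_bed_coordinates_convert_to_one_based_inclusive(self, bed):
        ts = seqio.load_targets(bed, adjacent_span=250_000)
        r = ts.regions[0]
        assert (r.start, r.end) == (400_000, 650_000)
        assert r.left_a == (150_000, 399_999)
        assert r.right_a == (650_001, 900_000)

    def test_adjacent_flank_clipped_at_chromosome_start(self, bed):
        ts = seqio.load_targets(bed, adjacent_span=250_000)
        r = ts.regions[1]
        assert r.left_a == (1, 100)          # shorter than the nominal span
        assert r.start == 101

    def test_two_targets_load_independently(self, bed):
        ts = seqio.load_targets(bed, adjacent_span=1000)
        assert len(ts) == 2
        assert {r.chrom for r in ts} == {"chr1", "chr2"}

    @pytest.mark.parametrize("line", ["chr1\tx\t100", "chr1\t100", "chr1\t200\t100"])
    def test_malformed_bed_reports_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\tok\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            seqio.load_targets(str(p))

    def test_bed_round_trip_is_identity(self, bed, tmp_path):
        ts = seqio.load_targets(bed, adjacent_span=2000)
        out = tmp_path / "again.bed"
        ts.write_bed(str(out))
        ts2 = seqio.load_targets(str(out), adjacent_span=2000)
        assert [(r.chrom, r.start, r.end, r.name) for r in ts] == \
            [(r.chrom, r.start, r.end, r.name) for r in ts2]

    @pytest.mark.parametrize("chrom,pos,code", [
        ("chr1", 525_000, "T"),     # target centre
        ("chr1", 300_000, "A"),     # 100 kb left of the capture span
        ("chr1", 10, "-"),
        ("chrX", 100, "-"),         # untargeted chromosome
    ])
    def test_classify_point(self, bed, chrom, pos, code):
        ts = seqio.load_targets(bed, adjacent_span=250_000)
        got, locus = ts.classify_point(chrom, pos)
        assert got == code
        assert (locus is None) == (code == "-")

    def test_classification_partitions_sampled_positions(self, bed):
        ts = seqio.load_targets(bed, adjacent_span=250_000)
        rng = np.random.default_rng(0)
        for pos in rng.integers(1, 1_000_000, 500):
            code, locus = ts.classify_point("chr1", int(pos))
            assert code in "TA-"
            t, a = 400_000 <= pos <= 650_000, 150_000 <= pos < 400_000 or 650_000 < pos <= 900_000
            assert code == ("T" if t else "A" if a else "-")


class TestGenome:
    def test_fetch_is_one_based_inclusive_uppercase(self):
        g = GenomeModel.from_sequences({"c": "acgtACGT"})
        assert g.fetch("c", 1, 4) == "ACGT"
        assert g.base("c", 5) == "A"
        with pytest.raises(ValueError):
            g.fetch("c", 0, 3)
        with pytest.raises(ValueError):
            g.fetch("c", 5, 9)

    def test_fasta_round_trip(self, tmp_path):
        g = GenomeModel.from_sequences({"chrA": "ACGT" * 50, "chrB": "TTTTGGGG"})
        path = tmp_path / "g.fa"
        g.write_fasta(str(path))
        g2 = GenomeModel.from_fasta(str(path))
        assert g2.chromosomes == g.chromosomes
        assert g2.fetch("chrA", 5, 12) == g.fetch("chrA", 5, 12)


def _write_sam(path, records, chroms=(("chr1", 100_000),)):
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": c, "LN": n} for c, n in chroms]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, flag, pos, cigar in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = "A" * sum(n for op, n in
                                         pysam.AlignedSegment.fromstring(
                                             f"x\t0\tchr1\t1\t0\t{cigar}\t*\t0\t0\t*\t*",
                                             out.header).cigartuples
                                         if op in (0, 1, 4))
            out.write(a)


class TestAlignmentGroups:
    def test_template_records_grouped_together(self, tmp_path):
        p = tmp_path / "a.sam"
        _write_sam(p, [("q1", 0x41, 100, "50M"), ("q1", 0x91, 300, "50M"),
                       ("q1", 0x841, 900, "20S30M"), ("q2", 0x41, 500, "50M")])
        groups = list(seqio.parse_alignment_groups(str(p), sample="s"))
        assert [len(g) for g in groups] == [3, 1]
        assert groups[0][2].is_supplementary

    def test_name_reappearing_later_is_an_error(self, tmp_path):
        p = tmp_path / "b.sam"
        _write_sam(p, [("q1", 0x41, 100, "50M"), ("q2", 0x41, 500, "50M"),
                       ("q1", 0x91, 300, "50M")])
        with pytest.raises(UngroupedInputError, match="name-sort"):
            list(seqio.parse_alignment_groups(str(p), sample="s"))

    def test_merged_single_end_record_flagged(self, tmp_path):
        p = tmp_path / "c.sam"
        _write_sam(p, [("q1", 0, 100, "80M")])
        (group,) = seqio.parse_alignment_groups(str(p), sample="s")
        assert group[0].is_merged


class TestBndVcf:
    def _sv(self, svid, n1, n2, svtype, metric=0, insert=""):
        sv = SVCall(id=svid, node1=n1, node2=n2, sv_type=svtype,
                    imprecise=False, supporters=[])
        sv.junction_metric = metric
        sv.insert_sequence = insert
        sv.target_class = "TT"
        return sv

    def test_round_trip_preserves_breakends_and_info(self, tiny_genome, tmp_path):
        svs = [
            self._sv("sv1", JunctionNode("chr1", 1010, "L"),
                     JunctionNode("chr1", 2000, "R"), "Del", metric=3),
            self._sv("sv2", JunctionNode("chr1", 1500, "L"),
                     JunctionNode("chr2", 900, "L"), "Trans", metric=-2, insert="TT"),
        ]
        out = tmp_path / "svs.vcf"
        seqio.write_bnd_vcf(svs, tiny_genome, str(out))
        recs = list(pysam.VariantFile(str(out)))
        assert len(recs) == 4
        by_id = {r.id: r for r in recs}
        # mutual mates with identical coordinates
        for r in recs:
            mate = by_id[r.info["MATEID"]]
            assert mate.info["MATEID"] == r.id
            assert r.info["SVTYPE"] == "BND"
        assert (by_id["sv1_1"].chrom, by_id["sv1_1"].pos) == ("chr1", 1010)
        assert (by_id["sv1_2"].chrom, by_id["sv1_2"].pos) == ("chr1", 2000)
        assert by_id["sv2_1"].info["JXNMETRIC"] == -2
        assert by_id["sv2_1"].info["INSSEQ"] == "TT"

    def test_bracket_orientation_classes(self, tiny_genome, tmp_path):
        deletion = self._sv("d", JunctionNode("chr1", 100, "L"),
                            JunctionNode("chr1", 900, "R"), "Del")
        inversion = self._sv("i", JunctionNode("chr1", 100, "L"),
                             JunctionNode("chr1", 900, "L"), "Inv")
        out = tmp_path / "o.vcf"
        seqio.write_bnd_vcf([deletion, inversion], tiny_genome, str(out))
        alts = {r.id: r.alts[0] for r in pysam.VariantFile(str(out))}
        # deletion: the two mates point in opposite directions
        assert "[" in alts["d_1"] and "]" in alts["d_2"]
        # inversion junction: both breakends share the bracket class
        assert "]" in alts["i_1"] and "]" in alts["i_2"]

    def test_out_of_bounds_breakend_skipped(self, tiny_genome, tmp_path):
        bad = self._sv("b", JunctionNode("chr1", 100, "L"),
                       JunctionNode("chr1", 99_999, "R"), "Del")
        out = tmp_path / "s.vcf"
        seqio.write_bnd_vcf([bad], tiny_genome, str(out))
        assert list(pysam.VariantFile(str(out))) == []
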