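import pytest

from capsv import junction as J
from capsv.molecule import collate_molecules
from capsv.seqio import AlignedSegment

from helpers import make_pair


def _mol(groups, mode="ligation"):
    mols, _ = collate_molecules(iter(groups), mode=mode, sample="S")
    assert len(mols) == 1
    return mols[0]


def _split_read_pair(qname="q", chrom1="chr1", p1_start=10_000, p1_end=10_099,
                     chrom2="chr1", p2_start=20_000, p2_end=20_050,
                     strand2="+", insert=""):
    """Read 1 split across a junction (primary + supplementary), read 2
    concordant within the second flank."""
    len1 = p1_end - p1_start + 1
    len2 = p2_end - p2_start + 1
    ins = len(insert)
    total = len1 + ins + len2
    seq = "A" * len1 + insert + "C" * len2
    primary = AlignedSegment(
        qname=qname, sample="S", chrom=chrom1, pos=p1_start, strand="+",
        cigar=[("M", len1), ("S", ins + len2)], mapq=60, seq=seq, qual=None,
        is_supplementary=False, is_read2=False, is_merged=False)
    if strand2 == "+":
        supp = AlignedSegment(
            qname=qname, sample="S", chrom=chrom2, pos=p2_start, strand="+",
            cigar=[("S", len1 + ins), ("M", len2)], mapq=60, seq=seq, qual=None,
            is_supplementary=True, is_read2=False, is_merged=False)
        mate_pos, mate_cigar = p2_start, [("M", len2)]
    else:
        # inverted second segment: the read continues into the minus strand
        supp = AlignedSegment(
            qname=qname, sample="S", chrom=chrom2, pos=p2_start, strand="-",
            cigar=[("M", len2), ("S", len1 + ins)], mapq=60, seq=seq, qual=None,
            is_supplementary=True, is_read2=False, is_merged=False)
        mate_pos, mate_cigar = p2_start, [("M", len2)]
    mate = AlignedSegment(
        qname=qname, sample="S", chrom=chrom2, pos=mate_pos,
        strand="-" if strand2 == "+" else "+",
        cigar=mate_cigar, mapq=60, seq="C" * len2, qual=None,
        is_supplementary=False, is_read2=True, is_merged=False)
    return [primary, supp, mate]


class TestNodeExtraction:
    def test_proper_pair_has_outer_nodes_only(self):
        mol = _mol([make_pair("q", "chr1", 1000, 1300)])
        outer, inner = J.extract_nodes(mol)
        assert (outer[0].pos, outer[0].side) == (1000, "R")
        assert (outer[1].pos, outer[1].side) == (1300, "L")
        assert all(n1 == n2 or True for n1, n2 in inner)  # structure only
        assert len(inner) <= 1  # at most the mate boundary

    def test_split_deletion_inner_nodes(self):
        mol = _mol([_split_read_pair()])
        _, inner = J.extract_nodes(mol)
        split_pairs = [p for i, p in enumerate(inner)
                       if mol.path.markers[i].kind == "split"]
        (exit_node, entry_node) = split_pairs[0]
        assert (exit_node.chrom, exit_node.pos, exit_node.side) == ("chr1", 10_099, "L")
        assert (entry_node.chrom, entry_node.pos, entry_node.side) == ("chr1", 20_000, "R")

    def test_inversion_split_yields_equal_sides(self):
        mol = _mol([_split_read_pair(strand2="-")])
        cands = J.call_candidates(mol, None, min_sv_size=50, max_proper_insert=1000)
        assert len(cands) == 1
        assert cands[0].sv_type == "Inv"
        assert cands[0].node1.side == cands[0].node2.side


class TestCandidateCalling:
    def test_split_deletion_candidate(self):
        mol = _mol([_split_read_pair()])
        cands = J.call_candidates(mol, None, min_sv_size=50, max_proper_insert=1000)
        assert [c.sv_type for c in cands] == ["Del"]
        assert cands[0].evidence == "split"
        assert mol.mol_class == "sv_candidate"

    def test_split_with_insert_records_inserted_bases(self):
        mol = _mol([_split_read_pair(insert="GGTT")])
        (cand,) = J.call_candidates(mol, None, min_sv_size=50, max_proper_insert=1000)
        assert cand.insert_len == 4
        assert cand.insert_seq == "GGTT"

    def test_translocation_candidate(self):
        mol = _mol([_split_read_pair(chrom2="chr2")])
        (cand,) = J.call_candidates(mol, None, min_sv_size=50, max_proper_insert=1000)
        assert cand.sv_type == "Trans"

    def test_far_pair_becomes_gap_candidate(self):
        mol = _mol([make_pair("q", "chr1", 10_000, 18_150, read_len=75)])
        (cand,) = J.call_candidates(mol, None, min_sv_size=50, max_proper_insert=1000)
        assert cand.evidence == "gap"
        assert cand.imprecise
        assert (cand.node1.pos, cand.node1.side) == (10_074, "L")
        assert (cand.node2.pos, cand.node2.side) == (18_076, "R")
        assert mol.mol_class == "gap_candidate"

    def test_concordant_pair_yields_no_candidates(self):
        mol = _mol([make_pair("q", "chr1", 10_000, 10_400, read_len=150)])
        assert J.call_candidates(mol, None, min_sv_size=50, max_proper_insert=1000) == []
        assert mol.mol_class == "proper"

    def test_small_junction_treated_as_indel(self):
        mol = _mol([_split_read_pair(p1_end=10_099, p2_start=10_130, p2_end=10_230)])
        assert J.call_candidates(mol, None, min_sv_size=50, max_proper_insert=1000) == []
        assert mol.mol_class == "proper"

    def test_candidate_nodes_canonically_sorted_twice_is_identity(self):
        mol = _mol([_split_read_pair(chrom1="chr2", chrom2="chr1")])
        (cand,) = J.call_candidates(mol, None, min_sv_size=50, max_proper_insert=1000,
                                    chrom_order={"chr1": 0, "chr2": 1})
        assert cand.node1.chrom == "chr1"


class TestSharedEndpoints:
    def test_candidate_sharing_outer_endpoint_flagged(self):
        sv_mol = _mol([_split_read_pair()])
        cands = J.call_candidates(sv_mol, None, min_sv_size=50, max_proper_insert=1000)
        proper = _mol([make_pair("p", "chr1", 10_000, 10_300)])
        # the SV molecule's left outer endpoint (10 000) pre-exists in the
        # library as a proper molecule endpoint
        idx = J.build_proper_endpoint_index([proper])
        J.flag_shared_endpoints(cands, idx)
        assert cands[0].shared_outer_endpoint

    def test_unique_endpoints_not_flagged(self):
        sv_mol = _mol([_split_read_pair()])
        cands = J.call_candidates(sv_mol, None, min_sv_size=50, max_proper_insert=1000)
        proper = _mol([make_pair("p", "chr1", 11_000, 11_300)])
        J.flag_shared_endpoints(cands, J.build_proper_endpoint_index([proper]))
        assert not cands[0].shared_outer_endpoint

    def test_empty_proper_index_flags_nothing(self):
        sv_mol = _mol([_split_read_pair()])
        cands = J.call_candidates(sv_mol, None, min_sv_size=50, max_proper_insert=1000)
        J.flag_shared_endpoints(cands, {})
        assert not cands[0].shared_outer_endpoint
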