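import random

import numpy as np
import pytest

from capsv import discovery as D
from capsv.junction import JunctionNode
from capsv.molecule import collate_molecules
from capsv.seqio import GenomeModel

from helpers import call_key, classify_calls, make_pair, placement_oracle


def _random_genome(seed, n=2, length=6000):
    gen = np.random.default_rng(seed)
    return GenomeModel.from_sequences(
        {f"chr{i + 1}": "".join("ACGT"[b] for b in gen.integers(0, 4, length))
         for i in range(n)})


class TestMicrohomologyMetric:
    def test_matches_placement_enumeration_oracle_on_random_junctions(self):
        genome = _random_genome(11)
        rng = random.Random(5)
        checked = 0
        for _ in range(400):
            c1, c2 = rng.choice(["chr1", "chr2"]), rng.choice(["chr1", "chr2"])
            p1 = rng.randrange(200, 5800)
            p2 = rng.randrange(200, 5800)
            s1, s2 = rng.choice("LR"), rng.choice("LR")
            if c1 == c2 and abs(p1 - p2) < 100:
                continue
            n1, n2 = JunctionNode(c1, p1, s1), JunctionNode(c2, p2, s2)
            kl, kr = D.junction_homology(genome, n1, n2)
            assert kl + kr == placement_oracle(genome, n1, n2)
            checked += 1
        assert checked > 300

    def test_planted_long_homology_recovered(self):
        # engineer a 9-base shared tract, the chimeric-PCR signature
        genome = _random_genome(3)
        n1, n2 = JunctionNode("chr1", 3000, "L"), JunctionNode("chr2", 2000, "R")
        tract = genome.fetch("chr1", 2992, 3000)
        genome.set_slice("chr2", 1991, tract)
        if genome.base("chr2", 1990) == genome.base("chr1", 2991):
            genome.set_slice("chr2", 1990, "ACGT"["TGCA".find(genome.base("chr1", 2991))])
        if genome.base("chr2", 2000) == genome.base("chr1", 3001):
            genome.set_slice("chr2", 2000, "ACGT"["TGCA".find(genome.base("chr1", 3001))])
        kl, kr = D.junction_homology(genome, n1, n2)
        assert kl + kr == 9
        assert kl + kr == placement_oracle(genome, n1, n2)


class _StubKey:
    def __init__(self, e1, e2):
        self.end1 = ("chr1", e1, "R")
        self.end2 = ("chr1", e2, "L")


class _StubMol:
    def __init__(self, mid, e1, e2, fam=(1, 0), sample="S"):
        self.id = mid
        self.sample = sample
        self.key = _StubKey(e1, e2)
        self.strand_family = list(fam)
        self.is_duplex = False
        self.shared_outer = False

    @property
    def n_read_pairs(self):
        return sum(self.strand_family)


def _call_with(mols):
    sups = [D.Supporter(m, "split") for m in mols]
    return D.SVCall(id="sv", node1=JunctionNode("chr1", 1000, "L"),
                    node2=JunctionNode("chr1", 2000, "R"), sv_type="Del",
                    imprecise=False, supporters=sups)


class TestNearDuplicatePurge:
    def test_sum_below_five_purges_lower_family(self):
        a = _StubMol("a", 100, 800, fam=(2, 1))
        b = _StubMol("b", 102, 802, fam=(1, 0))   # offsets (2, 2): sum 4 < 5
        sv = D.purge_near_duplicates(_call_with([a, b]))
        assert [s.molecule.id for s in sv.supporters] == ["a"]

    def test_sum_exactly_five_keeps_both(self):
        a = _StubMol("a", 100, 800)
        b = _StubMol("b", 103, 802)               # offsets (3, 2): sum 5
        sv = D.purge_near_duplicates(_call_with([a, b]))
        assert len(sv.supporters) == 2

    def test_distinct_molecules_untouched(self):
        a = _StubMol("a", 100, 800)
        b = _StubMol("b", 150, 860)
        assert len(D.purge_near_duplicates(_call_with([a, b])).supporters) == 2

    def test_purge_is_per_sample(self):
        a = _StubMol("a", 100, 800, sample="s1")
        b = _StubMol("b", 101, 801, sample="s2")
        assert len(D.purge_near_duplicates(_call_with([a, b])).supporters) == 2


class TestOuterClipRecovery:
    def _deletion_call(self, genome, p1, p2):
        sv = D.SVCall(id="sv1", node1=JunctionNode("chr1", p1, "L"),
                      node2=JunctionNode("chr1", p2, "R"), sv_type="Del",
                      imprecise=False, supporters=[])
        sv.junction_metric = 0
        return sv

    def _proper_with_exit_clip(self, genome, end, clip_seq):
        base = lambda p: genome.base("chr1", p)
        grp = make_pair("p", "chr1", end - 299, end, seq_by_pos=base,
                        clip_right=len(clip_seq), clip_right_seq=clip_seq)
        mols, _ = collate_molecules(iter([grp]), mode="ligation", sample="S")
        return mols[0]

    def test_matching_clip_recovered(self):
        genome = _random_genome(21, n=1)
        sv = self._deletion_call(genome, 2000, 4000)
        clip = genome.fetch("chr1", 4000, 4011)       # 12 bases of the far flank
        mol = self._proper_with_exit_clip(genome, 2000, clip)
        D.recover_outer_clips([mol], [sv], genome)
        assert sv.n_outer_clips == 1

    def test_short_clip_not_recovered(self):
        genome = _random_genome(22, n=1)
        sv = self._deletion_call(genome, 2000, 4000)
        mol = self._proper_with_exit_clip(genome, 2000, genome.fetch("chr1", 4000, 4002))
        D.recover_outer_clips([mol], [sv], genome)
        assert sv.n_outer_clips == 0

    def test_mismatching_clip_not_recovered(self):
        genome = _random_genome(23, n=1)
        sv = self._deletion_call(genome, 2000, 4000)
        wrong = genome.fetch("chr1", 4500, 4511)
        mol = self._proper_with_exit_clip(genome, 2000, wrong)
        D.recover_outer_clips([mol], [sv], genome)
        assert sv.n_outer_clips == 0


class TestGapReconstruction:
    def test_innermost_read_ends_define_nominal_nodes(self):
        from capsv.junction import JunctionCandidate

        def gap(p1, p2):
            return JunctionCandidate(
                molecule=_StubMol(f"m{p1}", p1 - 200, p2 + 200),
                node1=JunctionNode("chr1", p1, "L"),
                node2=JunctionNode("chr1", p2, "R"),
                evidence="gap", sv_type="Del", imprecise=True)

        n1, n2 = D.reconstruct_gap_junctions([gap(10_050, 19_990), gap(10_080, 19_970)])
        assert (n1.pos, n2.pos) == (10_080, 19_970)


class TestClassification:
    @pytest.mark.parametrize("p1,p2,expected", [
        # lig_run geometry: targets at [24001, 36000] per 60 kb chromosome,
        # adjacent flanks of 5 kb on either side
        (25_000, 30_000, "TT"),
        (25_000, 37_000, "TA"),
        (20_000, 37_000, "AA"),
        (25_000, 45_000, "t-"),
    ])
    def test_same_locus_uppercase(self, lig_run, p1, p2, expected):
        targets = lig_run["state"].targets
        sv = D.SVCall(id="x", node1=JunctionNode("chr1", p1, "L"),
                      node2=JunctionNode("chr1", p2, "R"), sv_type="Del",
                      imprecise=False, supporters=[])
        assert D.classify_sv(sv, targets) == expected

    def test_cross_target_lowercase(self, lig_run):
        targets = lig_run["state"].targets
        sv = D.SVCall(id="x", node1=JunctionNode("chr1", 25_000, "L"),
                      node2=JunctionNode("chr2", 25_000, "R"), sv_type="Trans",
                      imprecise=False, supporters=[])
        assert D.classify_sv(sv, targets) == "tt"


class TestClustering:
    def test_partition_is_order_independent(self, lig_run):
        state = lig_run["state"]
        cands = list(state.candidates)
        base = D.find_sv_sets(cands, state.max_proper_insert)
        rng = random.Random(9)
        for _ in range(3):
            rng.shuffle(cands)
            again = D.find_sv_sets(cands, state.max_proper_insert)
            assert sorted(map(call_key, base)) == sorted(map(call_key, again))
            assert sorted(sv.n_molecules for sv in base) == \
                sorted(sv.n_molecules for sv in again)

    def test_every_split_supported_truth_sv_called_exactly_once(self, lig_run):
        truth = lig_run["truth_junctions"]
        svs = lig_run["state"].svs_unfiltered
        sv_rows = truth[truth.kind == "sv"]
        keys = [call_key(sv) for sv in svs]
        for _, r in sv_rows.iterrows():
            k = (r.chrom1, int(r.pos1), r.side1, r.chrom2, int(r.pos2), r.side2)
            assert keys.count(k) == 1

    def test_read_pair_and_molecule_count_ordering(self, lig_run):
        for sv in lig_run["state"].svs_unfiltered:
            assert sv.n_read_pairs >= sv.n_molecules >= sv.n_duplex
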