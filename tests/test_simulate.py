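from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from capsv import simulate as S
from capsv.seqio import parse_alignment_groups


def _tiny_cfg(seed=33, **kw):
    base = dict(seed=seed, n_chroms=2, chrom_length=40_000, target_span=6_000,
                adjacent_span=4_000, depth=50,
                clones=[S.CloneSpec(fraction=0.5, n_svs=2)])
    base.update(kw)
    return S.SimConfig(**base)


class TestDeterminism:
    def test_same_config_gives_byte_identical_outputs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        S.simulate_run(_tiny_cfg(), str(a))
        S.simulate_run(_tiny_cfg(), str(b))
        for name in ("ref.fa", "targets.bed", "umis.txt", "S1.sam",
                     "S1.truth_pairs.tsv", "S1.truth_junctions.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_different_seed_changes_library(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        S.simulate_run(_tiny_cfg(seed=1), str(a))
        S.simulate_run(_tiny_cfg(seed=2), str(b))
        assert (a / "S1.sam").read_bytes() != (b / "S1.sam").read_bytes()


class TestTruthChannel:
    def test_every_read_name_has_exactly_one_truth_row(self, tmp_path):
        S.simulate_run(_tiny_cfg(ligation_chimera_rate=0.01), str(tmp_path))
        truth = pd.read_csv(tmp_path / "S1.truth_pairs.tsv", sep="\t")
        assert truth.qname.is_unique
        sam_names = {g[0].qname for g in
                     parse_alignment_groups(str(tmp_path / "S1.sam"), "S1")}
        assert sam_names == set(truth.qname)

    def test_sam_parses_and_is_name_grouped(self, tmp_path):
        S.simulate_run(_tiny_cfg(), str(tmp_path))
        groups = list(parse_alignment_groups(str(tmp_path / "S1.sam"), "S1"))
        assert all(len(g) >= 2 for g in groups)      # both mates present


class TestGeometry:
    def test_one_central_target_per_chromosome(self, tmp_path):
        cfg = _tiny_cfg(n_chroms=3)
        out = S.simulate_run(cfg, str(tmp_path))
        targets = out["targets"]
        assert len(targets) == 3
        for r in targets:
            assert r.t_length() == cfg.target_span
            assert r.left_a[1] - r.left_a[0] + 1 == cfg.adjacent_span
            assert r.right_a[1] - r.right_a[0] + 1 == cfg.adjacent_span

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            S.SimConfig(chrom_length=10_000, target_span=6_000,
                        adjacent_span=4_000).validate()


class TestArtifactSignatures:
    def test_chimeric_pcr_single_strand_single_read_pair_shared_endpoint(self, lig_run):
        pairs = lig_run["truth_pairs"]
        chim = pairs[pairs["class"] == "chimericPCR"]
        assert len(chim.fragment.unique()) >= 150
        per_frag = chim.groupby("fragment").agg(
            n=("qname", "count"), strands=("strand", "nunique"))
        assert (per_frag.n == 1).all()
        assert (per_frag.strands == 1).all()
        # one outer endpoint shared with a proper molecule from the library
        proper = pairs[pairs["class"] == "proper"]
        proper_ends = set(zip(proper.chrom1, proper.outer1)) | \
            set(zip(proper.chrom2, proper.outer2))
        chim_frags = chim.drop_duplicates("fragment")
        shared = sum(((r.chrom1, r.outer1) in proper_ends)
                     or ((r.chrom2, r.outer2) in proper_ends)
                     for r in chim_frags.itertuples())
        assert shared == len(chim_frags)

    def test_chimera_microhomology_peaks_at_eight_to_nine(self, lig_run):
        tj = lig_run["truth_junctions"]
        metrics = tj[tj.kind == "chimera"].metric.astype(int)
        assert (metrics >= 5).all()
        mode = metrics.value_counts().idxmax()
        assert mode in (8, 9)

    def test_ligation_junctions_blunt_or_single_at_insertion(self, lig_run):
        tj = lig_run["truth_junctions"]
        lig = tj[tj.kind == "ligation"]
        assert set(lig.metric.astype(int)) <= {0, -1}
        ins = lig[lig.metric.astype(int) == -1]["insert"]
        at = (ins.isin(["A", "T"])).mean()
        # post-shearing A-tailing: ~81% of one-base insertions are A or T
        assert abs(at - 0.81) < 0.12

    def test_true_sv_microhomology_short_or_small_insertion(self, lig_run):
        tj = lig_run["truth_junctions"]
        m = tj[tj.kind == "sv"].metric.astype(int)
        assert m.between(-8, 4).all()

    def test_ligation_second_endpoints_uniform_over_genome(self):
        # plan-level check with >= 2000 planted ligation junction sites
        cfg = S.SimConfig(seed=77, n_chroms=3, chrom_length=60_000,
                          target_span=15_000, adjacent_span=5_000,
                          depth=3000, ligation_chimera_rate=0.004)
        _, _, plan = S.make_genome(cfg)
        assert len(plan.ligation_sites) >= 2000
        pos = np.array([site.node_b.pos for site in plan.ligation_sites])
        margin = cfg.frag_mean + 3 * cfg.frag_sd + 60
        span = cfg.chrom_length - 2 * margin
        p = stats.kstest(pos, stats.uniform(loc=margin, scale=span).cdf).pvalue
        assert p > 0.01

    def test_foldbacks_are_small_inversions_with_large_homology(self, tag_run):
        tj = tag_run["truth_junctions"]
        fb = tj[tj.kind == "foldback"]
        assert len(fb) > 20
        assert (fb.side1 == fb.side2).all()                    # inversion nodes
        assert (abs(fb.pos2 - fb.pos1) < 1000).all()
        assert (fb.metric.astype(int) >= 8).all()

    def test_tagmentation_yields_no_duplex_molecules(self, tag_run):
        mols = tag_run["state"].molecules["S1"]
        assert all(not m.is_duplex for m in mols)


class TestCloneModel:
    def test_pure_clone_crossing_fraction_near_half_coverage(self, tmp_path):
        cfg = _tiny_cfg(seed=12, depth=150,
                        clones=[S.CloneSpec(fraction=1.0, n_svs=1)])
        out = S.simulate_run(cfg, str(tmp_path))
        pairs = pd.read_csv(tmp_path / "S1.truth_pairs.tsv", sep="\t")
        sv_frags = pairs[pairs["class"] == "trueSV"].fragment.nunique()
        # heterozygous SV in every cell: about half the molecules covering
        # the junction cross it
        expected = cfg.depth / 2
        assert abs(sv_frags - expected) < 4 * np.sqrt(expected)
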