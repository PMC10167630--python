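"""Synthetic probe-capture library simulator with ground truth.

The generator emulates a targeted capture sequencing experiment over a
small multi-chromosome genome: one central capture target per chromosome
with adjacent flanking regions, heterozygous SV-bearing clones mixed at
known fractions, duplex (ligated Y-adapter) or tagmentation library
chemistry, per-strand read-pair families, per-base sequencing error, and
the three major junction artifact classes with their characteristic
signatures:

* intermolecular ligation — two unrelated fragments joined before strand
  melting (duplex-capable), blunt or single A/T-base insertion junctions,
  second endpoints uniform over the genome;
* chimeric PCR — template switching at a shared k-mer (microhomology
  peaked at 8-9 bp) after strand melting: always single strand, one read
  pair, one outer endpoint shared with a proper library molecule;
* foldback inversion — small (< 1 kb) inversion junctions with large
  microhomology arising in tagmentation libraries.

Reads are emitted directly as aligned SAM records (split junction reads as
primary + supplementary with SA tags).  The emulated aligner is an
idealized maximal-placement aligner: alignment endpoints at junctions
follow the upstream-maximal microhomology placement determined by the
reference sequence, and isolated sequencing errors appear as mismatches
without perturbing placement.  Every emitted read pair has exactly one
ground-truth row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .discovery import junction_homology
from .junction import JunctionNode
from .seqio import GenomeModel, TargetRegion, TargetRegionSet, revcomp

_BASES = "ACGT"
_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class CloneSpec:
    """A cell clone present at `fraction` of the population, heterozygous
    for `n_svs` SVs per capture target (each SV on one haplotype)."""
    fraction: float
    n_svs: int = 0
    sv_type: str = "Del"
    size_range: tuple[int, int] = (150, 400)
    # junction metric distribution: positive = microhomology length,
    # 0 = blunt, negative = de novo insertion of that many bases
    metric_dist: dict[int, float] = field(default_factory=lambda: {
        1: 0.10, 2: 0.25, 3: 0.25, 4: 0.20, 0: 0.05,
        -1: 0.05, -2: 0.04, -4: 0.03, -6: 0.03})
    junction_snvs: tuple[tuple[str, int], ...] = ()   # (flank, distance) per SV


@dataclass
class SimConfig:
    """Study conditions for one simulated capture library."""
    seed: int = 0
    # genome / target geometry (capture-target design scaled down)
    n_chroms: int = 3
    chrom_length: int = 200_000
    target_span: int = 20_000
    adjacent_span: int = 20_000
    # library chemistry
    mode: str = "ligation_duplex"        # or 'tagmentation'
    depth: float = 500.0                 # molecule coverage over capture targets
    frag_mean: int = 300                 # sonication peak fragment size
    frag_sd: int = 40
    read_len: int = 151
    error_rate: float = 0.01             # per-base sequencing error
    umi_count: int = 96
    umi_length: int = 8
    family_zero_inflation: float = 0.3   # per-strand read-pair family: ZIP
    family_poisson_mean: float = 1.0
    fixed_family_size: Optional[int] = None   # overrides the ZIP draw per strand
    endpoint_jitter_prob: float = 0.05   # per replicate: 1 bp endpoint trim
    capture_prob: dict[str, float] = field(default_factory=lambda: {
        "T": 1.0, "A": 0.3, "-": 0.002})
    min_seg: int = 20                    # smallest alignable split segment
    low_mapq_fraction: float = 0.0
    low_mapq_value: int = 10
    # clone mixture (remainder of the population is SV-free background)
    clones: list[CloneSpec] = field(default_factory=list)
    # artifact rates per accepted library molecule
    ligation_chimera_rate: float = 0.0
    chimeric_pcr_rate: float = 0.0
    foldback_rate: float = 0.0
    chimera_mh_dist: dict[int, float] = field(default_factory=lambda: {
        6: 0.05, 7: 0.15, 8: 0.30, 9: 0.30, 10: 0.15, 11: 0.05})
    ligation_insert_prob: float = 0.5    # else blunt
    ligation_at_fraction: float = 0.81   # A/T among one-base insertions
    foldback_span: tuple[int, int] = (100, 900)
    foldback_mh_dist: dict[int, float] = field(default_factory=lambda: {
        8: 0.3, 9: 0.3, 10: 0.2, 11: 0.1, 12: 0.1})

    def validate(self) -> None:
        total = sum(c.fraction for c in self.clones)
        if total > 1.0 + 1e-9:
            raise ValueError("clone fractions sum to more than 1")
        for r in (self.ligation_chimera_rate, self.chimeric_pcr_rate, self.foldback_rate):
            if not 0 <= r <= 1:
                raise ValueError("artifact rates must be in [0, 1]")
        if self.mode not in ("ligation_duplex", "tagmentation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "tagmentation" and self.chimeric_pcr_rate < 0:
            raise ValueError("bad rate")
        if self.target_span + 2 * self.adjacent_span > self.chrom_length:
            raise ValueError("target plus adjacent flanks exceed chromosome length")

    @property
    def collate_mode(self) -> str:
        return "ligation" if self.mode == "ligation_duplex" else "tagmentation"


# ---------------------------------------------------------------------------
# Plan: junction sites engineered into the genome
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class PlannedJunction:
    jid: str
    kind: str                      # 'sv' | 'chimera' | 'ligation' | 'foldback'
    node_a: JunctionNode           # upstream flank, molecule order
    node_b: JunctionNode           # downstream flank, molecule order
    metric: int                    # realized junction metric (mh > 0, -len insert)
    insert_seq: str = ""
    clone_index: int = -1
    sv_type: str = ""
    snvs: tuple[tuple[str, int, str, int, str], ...] = ()  # (flank, dist, chrom, pos, alt)

    def canonical_nodes(self, chrom_order: dict[str, int]
                        ) -> tuple[JunctionNode, JunctionNode]:
        if self.node_a.sort_key(chrom_order) <= self.node_b.sort_key(chrom_order):
            return self.node_a, self.node_b
        return self.node_b, self.node_a


@dataclass
class SimPlan:
    sv_junctions: list[PlannedJunction]
    chimera_sites: list[PlannedJunction]
    ligation_sites: list[PlannedJunction]
    foldback_sites: list[PlannedJunction]
    umis: list[str]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def make_umi_whitelist(rng: np.random.Generator, count: int, length: int,
                       min_dist: int = 3) -> list[str]:
    """Expected-UMI set with pairwise Hamming distance >= min_dist so that
    single-mismatch matching stays unambiguous."""
    umis: list[str] = []
    while len(umis) < count:
        cand = _rand_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, u)) >= min_dist for u in umis):
            umis.append(cand)
    return umis


class _SiteReserver:
    """Tracks reserved breakpoint neighborhoods so planted junctions do not
    interfere with each other."""

    def __init__(self, pad: int = 2):
        self.pad = pad
        self.taken: dict[str, list[tuple[int, int]]] = {}

    def free(self, chrom: str, lo: int, hi: int) -> bool:
        for a, b in self.taken.get(chrom, ()):
            if lo <= b + self.pad and a <= hi + self.pad:
                return False
        return True

    def reserve(self, chrom: str, lo: int, hi: int) -> None:
        self.taken.setdefault(chrom, []).append((lo, hi))


def _flank_ref_pos(node: JunctionNode, offset: int, before: bool) -> int:
    """Reference position of the j-th base before (toward the flank) or
    after (across the junction) the node, in molecule orientation."""
    if before:
        return node.pos - (offset - 1) if node.side == "L" else node.pos + (offset - 1)
    return node.pos + offset if node.side == "L" else node.pos - offset


def _set_matching(genome: GenomeModel, chrom: str, pos: int,
                  value: str, same_strand: bool) -> None:
    genome.set_slice(chrom, pos, value if same_strand else _COMP1[value])


def _plant_junction(genome: GenomeModel, rng: np.random.Generator,
                    node_a: JunctionNode, node_b: JunctionNode,
                    mh: int, insert_len: int,
                    insert_seq: Optional[str] = None) -> str:
    """Engineer the reference so the junction's realized signature equals
    the request: microhomology tract of exactly `mh` bases at the upstream
    placement extreme (downstream extension zero), or a de novo insert of
    `insert_len` bases matching neither flank.  Returns the insert
    sequence ('' for mh junctions)."""
    # orientation bookkeeping: bases on each flank are read forward for
    # side L (upstream) / side R (downstream) and reverse-complemented
    # otherwise
    a_fwd_before = node_a.side == "L"
    b_fwd = node_b.side == "R"

    def get(chrom, pos, fwd):
        b = genome.base(chrom, pos)
        return b if fwd else _COMP1[b]

    def a_before(j):
        return get(node_a.chrom,
                   node_a.pos - (j - 1) if a_fwd_before else node_a.pos + (j - 1),
                   a_fwd_before)

    def b_ext_before_pos(j):
        return node_b.pos - j if b_fwd else node_b.pos + j

    def a_ext_after_pos(j):
        return node_a.pos + j if a_fwd_before else node_a.pos - j

    def b_after(j):
        return get(node_b.chrom,
                   node_b.pos + (j - 1) if b_fwd else node_b.pos - (j - 1), b_fwd)

    def other_base(value):
        return _BASES[(_BASES.index(value) + 1 + rng.integers(0, 3)) % 4]

    if insert_len > 0:
        ins = insert_seq if insert_seq is not None else _rand_seq(rng, insert_len)
        # the insert must match neither flank's continuation; a requested
        # insert (e.g. the A-tailing base) is kept by adjusting the guard
        # bases instead
        a_after1 = get(node_a.chrom, a_ext_after_pos(1), a_fwd_before)
        if ins[0] == a_after1:
            if insert_seq is None:
                ins = other_base(a_after1) + ins[1:]
            else:
                _set_matching(genome, node_a.chrom, a_ext_after_pos(1),
                              other_base(ins[0]), a_fwd_before)
        b_before1 = get(node_b.chrom, b_ext_before_pos(1), b_fwd)
        if ins[-1] == b_before1:
            if insert_seq is None:
                ins = ins[:-1] + other_base(b_before1)
            else:
                _set_matching(genome, node_b.chrom, b_ext_before_pos(1),
                              other_base(ins[-1]), b_fwd)
        return ins

    # plant the homology tract: flank B's backward reference extension
    # mirrors the last mh bases of flank A
    for j in range(1, mh + 1):
        _set_matching(genome, node_b.chrom, b_ext_before_pos(j), a_before(j), b_fwd)
    # break the tract on both sides so the realized metric is exact
    a_next = a_before(mh + 1)
    if get(node_b.chrom, b_ext_before_pos(mh + 1), b_fwd) == a_next:
        _set_matching(genome, node_b.chrom, b_ext_before_pos(mh + 1),
                      other_base(a_next), b_fwd)
    b_first = b_after(1)
    if get(node_a.chrom, a_ext_after_pos(1), a_fwd_before) == b_first:
        _set_matching(genome, node_a.chrom, a_ext_after_pos(1),
                      other_base(b_first), a_fwd_before)
    return ""


def _draw_from_dist(rng: np.random.Generator, dist: dict[int, float]) -> int:
    keys = sorted(dist)
    w = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=w / w.sum()))


def _expected_accepted(cfg: SimConfig) -> float:
    delta = cfg.depth / cfg.frag_mean
    t_len = cfg.n_chroms * cfg.target_span
    a_len = cfg.n_chroms * 2 * cfg.adjacent_span
    rest = cfg.n_chroms * cfg.chrom_length - t_len - a_len
    p = cfg.capture_prob
    return delta * (t_len + cfg.n_chroms * cfg.frag_mean) \
        + delta * p["A"] * a_len + delta * p["-"] * rest


def make_genome(cfg: SimConfig) -> tuple[GenomeModel, TargetRegionSet, SimPlan]:
    """Random-composition chromosomes, one central capture target per
    chromosome with adjacent flanks, and the engineered junction plan
    (clone SVs plus pre-placed artifact junction sites).  Deterministic
    under cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    seqs = {f"chr{i + 1}": _rand_seq(rng, cfg.chrom_length)
            for i in range(cfg.n_chroms)}
    genome = GenomeModel.from_sequences(seqs)
    regions = []
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        start = (cfg.chrom_length - cfg.target_span) // 2 + 1
        end = start + cfg.target_span - 1
        regions.append(TargetRegion(
            name=f"T{i + 1}", chrom=chrom, start=start, end=end,
            adjacent_span=cfg.adjacent_span,
            left_a=(max(1, start - cfg.adjacent_span), start - 1),
            right_a=(end + 1, min(cfg.chrom_length, end + cfg.adjacent_span))))
    targets = TargetRegionSet(regions)
    reserver = _SiteReserver()
    hard_reserver = _SiteReserver()   # SV/chimera/foldback edit zones only
    margin = cfg.frag_mean + 3 * cfg.frag_sd + 60

    def sample_t_pos(chrom_i: int, rng) -> int:
        r = regions[chrom_i]
        return int(rng.integers(r.start + margin, r.end - margin + 1))

    # ---- clone SVs (heterozygous, both breakpoints inside one target) ----
    sv_junctions: list[PlannedJunction] = []
    for ci, clone in enumerate(cfg.clones):
        for k in range(clone.n_svs):
            chrom_i = k % cfg.n_chroms
            r = regions[chrom_i]
            for _attempt in range(4000):
                size = int(rng.integers(clone.size_range[0], clone.size_range[1] + 1))
                p1 = sample_t_pos(chrom_i, rng)
                p2 = p1 + size
                if p2 > r.end - margin:
                    continue
                if not reserver.free(r.chrom, p1 - 40, p2 + 40):
                    continue
                break
            else:
                raise RuntimeError("could not place clone SV; enlarge targets")
            # spacing keeps junction clusters separable and precludes
            # fragments crossing two junctions
            reserver.reserve(r.chrom, p1 - 450, p2 + 450)
            hard_reserver.reserve(r.chrom, p1 - 20, p2 + 20)
            metric = _draw_from_dist(rng, clone.metric_dist)
            if clone.sv_type == "Del":
                node_a = JunctionNode(r.chrom, p1, "L")
                node_b = JunctionNode(r.chrom, p2, "R")
            elif clone.sv_type == "Dup":
                node_a = JunctionNode(r.chrom, p2, "L")
                node_b = JunctionNode(r.chrom, p1, "R")
            else:
                raise ValueError("clone SVs support Del and Dup")
            ins = _plant_junction(genome, rng, node_a, node_b,
                                  max(metric, 0), max(-metric, 0))
            if metric >= 0:
                kl, kr = junction_homology(genome, node_a, node_b)
                assert (kl, kr) == (metric, 0), (kl, kr, metric)
            snvs = []
            for flank, dist in clone.junction_snvs:
                node = node_a if flank == "left" else node_b
                mh_here = max(metric, 0) if flank == "left" else 0
                j = mh_here + dist
                pos = _flank_ref_pos(node, j, before=True)
                ref = genome.base(node.chrom, pos)
                alt = _BASES[(_BASES.index(ref) + 1) % 4]
                snvs.append((flank, dist, node.chrom, pos, alt))
            sv_junctions.append(PlannedJunction(
                jid=f"sv_j{len(sv_junctions) + 1}", kind="sv",
                node_a=node_a, node_b=node_b,
                metric=metric, insert_seq=ins, clone_index=ci,
                sv_type=clone.sv_type, snvs=tuple(snvs)))

    expected = _expected_accepted(cfg)


    placed_pairs: list[tuple[JunctionNode, JunctionNode]] = []

    def junction_is_distinct(na: JunctionNode, nb: JunctionNode,
                             sep: int = 700) -> bool:
        """Distinct artifact junctions must not co-cluster: no existing
        planned junction may have both nodes within one insert-size of the
        new one (in either node pairing)."""
        def close(x: JunctionNode, y: JunctionNode) -> bool:
            return (x.chrom == y.chrom and x.side == y.side
                    and abs(x.pos - y.pos) < sep)

        for oa, ob in placed_pairs:
            if (close(na, oa) and close(nb, ob)) or \
                    (close(na, ob) and close(nb, oa)):
                return False
        return True

    def plan_sites(kind: str, rate: float, make) -> list[PlannedJunction]:
        if rate <= 0:
            return []
        n = int(np.ceil(rate * expected * 1.25)) + 8
        return [make(i) for i in range(n)]

    def make_chimera(i: int) -> PlannedJunction:
        for _ in range(4000):
            ca, cb = rng.integers(0, cfg.n_chroms, size=2)
            pa = sample_t_pos(int(ca), rng)
            pb = sample_t_pos(int(cb), rng)
            # template switching can anneal in either orientation, so
            # chimeric junctions appear as any SV type
            na = JunctionNode(regions[ca].chrom, int(pa),
                              "L" if rng.random() < 0.5 else "R")
            nb = JunctionNode(regions[cb].chrom, int(pb),
                              "R" if rng.random() < 0.5 else "L")
            if na.chrom == nb.chrom and abs(na.pos - nb.pos) < 2000:
                continue
            if not junction_is_distinct(na, nb):
                continue
            # edit zones: ~1 base past node_a, up to mh+1 bases before node_b
            if reserver.free(na.chrom, na.pos - 2, na.pos + 3) and \
                    reserver.free(nb.chrom, nb.pos - 15, nb.pos + 2):
                break
        else:
            raise RuntimeError("could not place chimera site")
        placed_pairs.append((na, nb))
        reserver.reserve(na.chrom, na.pos - 2, na.pos + 3)
        reserver.reserve(nb.chrom, nb.pos - 15, nb.pos + 2)
        hard_reserver.reserve(na.chrom, na.pos - 2, na.pos + 3)
        hard_reserver.reserve(nb.chrom, nb.pos - 15, nb.pos + 2)
        mh = _draw_from_dist(rng, cfg.chimera_mh_dist)
        _plant_junction(genome, rng, na, nb, mh, 0)
        kl, kr = junction_homology(genome, na, nb)
        return PlannedJunction(jid=f"chim{i + 1}", kind="chimera",
                               node_a=na, node_b=nb, metric=kl + kr)

    def make_ligation(i: int) -> PlannedJunction:
        glen = cfg.n_chroms * cfg.chrom_length
        for _ in range(2000):
            ca = int(rng.integers(0, cfg.n_chroms))
            pa = sample_t_pos(ca, rng)
            gpos = int(rng.integers(0, glen))   # uniform over the genome
            cb = gpos // cfg.chrom_length
            pb = gpos % cfg.chrom_length + 1
            if not margin <= pb <= cfg.chrom_length - margin:
                continue  # resample; keeps the second endpoint uniform
            side_a = "L" if rng.random() < 0.5 else "R"
            side_b = "R" if rng.random() < 0.5 else "L"
            na = JunctionNode(regions[ca].chrom, pa, side_a)
            nb = JunctionNode(f"chr{cb + 1}", pb, side_b)
            if na.chrom == nb.chrom and abs(na.pos - nb.pos) < 2000:
                continue
            if not junction_is_distinct(na, nb):
                continue
            # the second endpoint must stay uniform over the genome:
            # avoid only the engineered SV/chimera/foldback edit zones,
            # not the dense ligation-site zones themselves
            if reserver.free(na.chrom, na.pos - 3, na.pos + 3) and \
                    hard_reserver.free(nb.chrom, nb.pos - 2, nb.pos + 2):
                break
        else:
            raise RuntimeError("could not place ligation site")
        placed_pairs.append((na, nb))
        reserver.reserve(na.chrom, na.pos - 3, na.pos + 3)
        if rng.random() < cfg.ligation_insert_prob:
            if rng.random() < cfg.ligation_at_fraction:
                base = "A" if rng.random() < 0.5 else "T"
            else:
                base = "C" if rng.random() < 0.5 else "G"
            ins = _plant_junction(genome, rng, na, nb, 0, 1, insert_seq=base)
            metric = -1
        else:
            _plant_junction(genome, rng, na, nb, 0, 0)
            kl, kr = junction_homology(genome, na, nb)
            metric, ins = kl + kr, ""
        return PlannedJunction(jid=f"lig{i + 1}", kind="ligation",
                               node_a=na, node_b=nb, metric=metric,
                               insert_seq=ins)

    def make_foldback(i: int) -> PlannedJunction:
        for _ in range(2000):
            ca = int(rng.integers(0, cfg.n_chroms))
            p1 = sample_t_pos(ca, rng)
            span = int(rng.integers(cfg.foldback_span[0], cfg.foldback_span[1] + 1))
            p2 = p1 - span
            na = JunctionNode(regions[ca].chrom, p1, "L")
            nb = JunctionNode(regions[ca].chrom, p2, "L")
            # only the homology edit zones need exclusivity, not the span;
            # foldbacks are dense local hairpins and are exempt from the
            # junction-distinctness spacing
            if reserver.free(na.chrom, p1 - 2, p1 + 3) and \
                    reserver.free(na.chrom, p2 - 2, p2 + 16):
                break
        else:
            raise RuntimeError("could not place foldback site")
        reserver.reserve(na.chrom, p1 - 2, p1 + 3)
        reserver.reserve(na.chrom, p2 - 2, p2 + 16)
        hard_reserver.reserve(na.chrom, p1 - 2, p1 + 3)
        hard_reserver.reserve(na.chrom, p2 - 2, p2 + 16)
        mh = _draw_from_dist(rng, cfg.foldback_mh_dist)
        _plant_junction(genome, rng, na, nb, mh, 0)
        kl, kr = junction_homology(genome, na, nb)
        return PlannedJunction(jid=f"fb{i + 1}", kind="foldback",
                               node_a=na, node_b=nb, metric=kl + kr)

    plan = SimPlan(
        sv_junctions=sv_junctions,
        chimera_sites=plan_sites("chimera", cfg.chimeric_pcr_rate, make_chimera),
        ligation_sites=plan_sites("ligation", cfg.ligation_chimera_rate, make_ligation),
        foldback_sites=(plan_sites("foldback", cfg.foldback_rate, make_foldback)
                        if cfg.mode == "tagmentation" else []),
        umis=make_umi_whitelist(rng, cfg.umi_count, cfg.umi_length),
    )
    return genome, targets, plan


# ---------------------------------------------------------------------------
# Clone haplotype model
# ---------------------------------------------------------------------------

class _ChromHap:
    """Block model of one haplotype of one chromosome: alternating
    reference intervals and junction inserts, with hap-coordinate lookup
    (0-based) and junction boundaries."""

    def __init__(self, blocks: list[tuple], jids: list[Optional[str]]):
        self.blocks = blocks          # ('ref', start, end) | ('ins', seq, jid)
        self.jids = jids              # jid of the boundary AFTER block i
        lens = [(e - s + 1) if b[0] == "ref" else len(b[1])
                for b in blocks for s, e in [(b[1], b[2]) if b[0] == "ref" else (1, len(b[1]))]]
        self.lens = lens
        self.cum = np.concatenate([[0], np.cumsum(lens)])
        self.total = int(self.cum[-1])
        self.boundaries = self.cum[1:-1]

    def block_index(self, hap_pos: int) -> int:
        return int(np.searchsorted(self.cum, hap_pos, side="right") - 1)

    def ref_pos(self, hap_pos: int) -> tuple[str | None, int]:
        i = self.block_index(hap_pos)
        b = self.blocks[i]
        off = hap_pos - int(self.cum[i])
        if b[0] == "ref":
            return "ref", b[1] + off
        return None, 0

    def crosses(self, s: int, e: int) -> bool:
        """True when fragment [s, e) spans a block boundary."""
        lo = np.searchsorted(self.boundaries, s, side="right")
        hi = np.searchsorted(self.boundaries, e - 1, side="right")
        return hi > lo

    def parts_for(self, chrom: str, s: int, e: int) -> tuple[list, list[str]]:
        """Molecule parts covering fragment [s, e) and the jids of crossed
        junction boundaries."""
        parts, jids = [], []
        i = self.block_index(s)
        pos = s
        while pos < e:
            b = self.blocks[i]
            bstart = int(self.cum[i])
            bend = int(self.cum[i + 1])
            lo, hi = pos, min(e, bend)
            if b[0] == "ref":
                parts.append(("ref", chrom, b[1] + (lo - bstart),
                              b[1] + (hi - 1 - bstart), "+"))
            else:
                parts.append(("ins", b[1][lo - bstart:hi - bstart]))
            if hi == bend and hi < e and self.jids[i]:
                jids.append(self.jids[i])
            pos = hi
            i += 1
        return parts, list(dict.fromkeys(jids))


def _build_hap(cfg: SimConfig, plan: SimPlan, clone_index: int,
               chrom: str) -> _ChromHap:
    """Variant haplotype blocks for one clone on one chromosome."""
    L = cfg.chrom_length
    events = [j for j in plan.sv_junctions
              if j.clone_index == clone_index and j.node_a.chrom == chrom]
    if not events:
        return _ChromHap([("ref", 1, L)], [None])

    def sort_pos(j):
        return min(j.node_a.pos, j.node_b.pos)

    events.sort(key=sort_pos)
    blocks: list[tuple] = []
    jids: list[Optional[str]] = []
    cur = 1
    for j in events:
        if j.sv_type == "Del":
            p1, p2 = j.node_a.pos, j.node_b.pos
            blocks.append(("ref", cur, p1))
            jids.append(j.jid)
            cur = p2
        elif j.sv_type == "Dup":
            p2, p1 = j.node_a.pos, j.node_b.pos   # node_a = (p2, L), node_b = (p1, R)
            blocks.append(("ref", cur, p2))
            jids.append(j.jid)
            cur = p1
        if j.insert_seq:
            blocks.append(("ins", j.insert_seq, j.jid))
            jids.append(j.jid)
    blocks.append(("ref", cur, L))
    jids.append(None)
    return _ChromHap(blocks, jids)


# ---------------------------------------------------------------------------
# Molecule descriptors and read emission
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class _MolDesc:
    fid: int
    parts: list        # ('ref', chrom, start, end, strand) | ('ins', seq)
    cls: str           # proper | trueSV | ligation | chimericPCR | foldback
    jid: str
    fam: tuple[int, int]
    mapq: int
    umi: Optional[tuple[int, int]]
    overlay: Optional[list[tuple[str, int, str]]] = None


def _flip_parts(parts: list) -> list:
    out = []
    for p in reversed(parts):
        if p[0] == "ref":
            out.append(("ref", p[1], p[2], p[3], "-" if p[4] == "+" else "+"))
        else:
            out.append(("ins", revcomp(p[1])))
    return out


def _part_len(p) -> int:
    return (p[3] - p[2] + 1) if p[0] == "ref" else len(p[1])


def _mol_seq(seqs: dict[str, str], parts: list,
             overlay: Optional[list[tuple[str, int, str]]]) -> str:
    chunks = []
    for p in parts:
        if p[0] == "ins":
            chunks.append(p[1])
            continue
        _, chrom, s, e, strand = p
        piece = seqs[chrom][s - 1:e]
        if overlay:
            for oc, opos, alt in overlay:
                if oc == chrom and s <= opos <= e:
                    i = opos - s
                    piece = piece[:i] + alt + piece[i + 1:]
        chunks.append(piece if strand == "+" else revcomp(piece))
    return "".join(chunks)


def _entry_exit(parts: list) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
    first = next(p for p in parts if p[0] == "ref")
    last = next(p for p in reversed(parts) if p[0] == "ref")
    entry = (first[1], first[2], "R") if first[4] == "+" else (first[1], first[3], "L")
    exit_ = (last[1], last[3], "L") if last[4] == "+" else (last[1], last[2], "R")
    return entry, exit_


class _SamWriter:
    def __init__(self, path: str, genome: GenomeModel):
        self.fh = open(path, "w")
        lines = ["@HD\tVN:1.6\tSO:unsorted\tGO:query"]
        for name, length in genome.chromosomes:
            lines.append(f"@SQ\tSN:{name}\tLN:{length}")
        lines.append("@PG\tID:capsv-sim\tPN:capsv-sim")
        self.fh.write("\n".join(lines) + "\n")
        self.buf: list[str] = []

    def add(self, line: str) -> None:
        self.buf.append(line)
        if len(self.buf) >= 50_000:
            self.flush()

    def flush(self) -> None:
        if self.buf:
            self.fh.write("\n".join(self.buf) + "\n")
            self.buf = []

    def close(self) -> None:
        self.flush()
        self.fh.close()


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    arr = bytearray(seq.encode())
    pos = rng.integers(0, len(seq), size=k)
    shift = rng.integers(1, 4, size=k)
    for p, sh in zip(pos, shift):
        cur = _BASES.find(chr(arr[p]))
        if cur >= 0:
            arr[p] = ord(_BASES[(cur + sh) % 4])
    return arr.decode()


def _read_segments(parts: list, a: int, b: int, min_seg: int) -> list[dict]:
    """Aligned segments of the read window [a, b) on the oriented
    molecule: each alignable reference part overlap of >= min_seg bases."""
    segs = []
    fs = 0
    for p in parts:
        fl = _part_len(p)
        fe = fs + fl
        if p[0] == "ref":
            lo, hi = max(a, fs), min(b, fe)
            if hi - lo > 0:
                off_lo, off_hi = lo - fs, hi - fs
                if p[4] == "+":
                    rs, re = p[2] + off_lo, p[2] + off_hi - 1
                else:
                    rs, re = p[3] - (off_hi - 1), p[3] - off_lo
                segs.append(dict(chrom=p[1], rs=rs, re=re, strand=p[4],
                                 pre=lo - a, mlen=hi - lo, post=b - hi))
        fs = fe
    big = [s for s in segs if s["mlen"] >= min_seg]
    if big:
        return big
    return sorted(segs, key=lambda s: -s["mlen"])[:1]


def _extend_single_segment(seg: dict, window: str, seqs: dict[str, str]) -> None:
    """Maximal-aligner emulation for a read with a single aligned segment:
    clipped bases that match the reference continuation are absorbed into
    the alignment.  Extension is decided on the error-free molecule
    sequence, so placement is reference-determined (clips shrink to the
    bases that genuinely diverge, e.g. across a junction microhomology)."""
    ref = seqs[seg["chrom"]]
    n = len(ref)
    if seg["strand"] == "+":
        while seg["pre"] > 0 and seg["rs"] > 1 \
                and window[seg["pre"] - 1] == ref[seg["rs"] - 2]:
            seg["pre"] -= 1
            seg["rs"] -= 1
            seg["mlen"] += 1
        while seg["post"] > 0 and seg["re"] < n \
                and window[seg["pre"] + seg["mlen"]] == ref[seg["re"]]:
            seg["post"] -= 1
            seg["re"] += 1
            seg["mlen"] += 1
    else:
        while seg["pre"] > 0 and seg["re"] < n \
                and window[seg["pre"] - 1] == _COMP1.get(ref[seg["re"]], "N"):
            seg["pre"] -= 1
            seg["re"] += 1
            seg["mlen"] += 1
        while seg["post"] > 0 and seg["rs"] > 1 \
                and window[seg["pre"] + seg["mlen"]] == _COMP1.get(ref[seg["rs"] - 2], "N"):
            seg["post"] -= 1
            seg["rs"] -= 1
            seg["mlen"] += 1


def _flip_strand(s: str) -> str:
    return "-" if s == "+" else "+"


def _cigar_of(seg: dict, rec_strand_flip: bool) -> str:
    pre, m, post = seg["pre"], seg["mlen"], seg["post"]
    if rec_strand_flip:
        pre, post = post, pre
    out = []
    if pre:
        out.append(f"{pre}S")
    out.append(f"{m}M")
    if post:
        out.append(f"{post}S")
    return "".join(out)


def _emit_molecule(sam: _SamWriter, truth: list[str], desc: _MolDesc,
                   cfg: SimConfig, rng: np.random.Generator,
                   seqs: dict[str, str], sample: str,
                   umi_seqs: Optional[list[str]]) -> None:
    base_parts = desc.parts
    flipped = _flip_parts(base_parts) if desc.fam[1] > 0 else None
    entry, exit_ = _entry_exit(base_parts)
    for strand in (0, 1):
        n_rep = desc.fam[strand]
        if n_rep == 0:
            continue
        parts0 = base_parts if strand == 0 else flipped
        for rep in range(n_rep):
            parts = parts0
            if (cfg.endpoint_jitter_prob > 0 and len(parts0) == 1
                    and parts0[0][0] == "ref"
                    and rng.random() < cfg.endpoint_jitter_prob):
                _, c, s, e, st = parts0[0]
                if rng.random() < 0.5:
                    parts = [("ref", c, s + 1, e, st)]
                else:
                    parts = [("ref", c, s, e - 1, st)]
            mol = _mol_seq(seqs, parts, desc.overlay)
            L = len(mol)
            rl = min(cfg.read_len, L)
            qname = f"{sample}.f{desc.fid}.s{strand}.r{rep}"
            windows = [(0, rl, False), (max(0, L - rl), L, True)]
            reads = []
            cleans = [mol[a:b] for a, b, _ in windows]
            seg_sets = [_read_segments(parts, a, b, cfg.min_seg)
                        for a, b, _ in windows]
            # clip extension through junction homology applies only when
            # neither mate sequences the junction as a split: placements
            # within one template stay consistent
            if max(len(s) for s in seg_sets) == 1:
                for clean, segs in zip(cleans, seg_sets):
                    if segs[0]["pre"] or segs[0]["post"]:
                        _extend_single_segment(segs[0], clean, seqs)
            for (a, b, is_r2), clean, segs in zip(windows, cleans, seg_sets):
                ff = _apply_errors(clean, rng, cfg.error_rate)
                reads.append((ff, segs, is_r2))
            mate_primary = []
            for ff, segs, is_r2 in reads:
                prim = max(segs, key=lambda s: s["mlen"])
                rec_strand = prim["strand"] if not is_r2 else _flip_strand(prim["strand"])
                mate_primary.append((prim["chrom"], prim["rs"], rec_strand))
            rx = ""
            if umi_seqs is not None and desc.umi is not None:
                u1, u2 = desc.umi if strand == 0 else (desc.umi[1], desc.umi[0])
                rx_val = (_apply_errors(umi_seqs[u1 - 1], rng, cfg.error_rate)
                          + "-" + _apply_errors(umi_seqs[u2 - 1], rng, cfg.error_rate))
                rx = f"\tRX:Z:{rx_val}"
            for ridx, (ff, segs, is_r2) in enumerate(reads):
                mchrom, mpos, mstrand = mate_primary[1 - ridx]
                prim = max(segs, key=lambda s: s["mlen"])
                sa_items = []
                if len(segs) > 1:
                    for s in segs:
                        rstr = s["strand"] if not is_r2 else _flip_strand(s["strand"])
                        sa_items.append((s, rstr))
                for s in segs:
                    rec_strand = s["strand"] if not is_r2 else _flip_strand(s["strand"])
                    flag = 0x1
                    flag |= 0x80 if is_r2 else 0x40
                    if rec_strand == "-":
                        flag |= 0x10
                    if mstrand == "-":
                        flag |= 0x20
                    is_supp = s is not prim
                    if is_supp:
                        flag |= 0x800
                    # stored SEQ/CIGAR are in the alignment's reference-forward
                    # orientation, which follows the molecule part's strand
                    seq_out = ff if s["strand"] == "+" else revcomp(ff)
                    cig = _cigar_of(s, s["strand"] == "-")
                    tags = [f"MQ:i:{desc.mapq}"]
                    if sa_items:
                        others = [o for o, _ in sa_items if o is not s]
                        sa = "".join(
                            f"{o['chrom']},{o['rs']},"
                            f"{(o['strand'] if not is_r2 else _flip_strand(o['strand']))},"
                            f"{_cigar_of(o, o['strand'] == '-')},"
                            f"{desc.mapq},0;" for o in others)
                        tags.append(f"SA:Z:{sa}")
                    tag_txt = "\t".join(tags)
                    sam.add(f"{qname}\t{flag}\t{s['chrom']}\t{s['rs']}\t{desc.mapq}\t"
                            f"{cig}\t{mchrom}\t{mpos}\t0\t{seq_out}\t{'I' * len(seq_out)}"
                            f"\t{tag_txt}{rx}")
            truth.append(f"{qname}\t{sample}\t{desc.fid}\t{desc.cls}\t{desc.jid}\t"
                         f"{strand}\t{rep}\t{entry[0]}\t{entry[1]}\t{entry[2]}\t"
                         f"{exit_[0]}\t{exit_[1]}\t{exit_[2]}\t{len(base_parts)}")


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def _draw_frag_lengths(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    lens = rng.normal(cfg.frag_mean, cfg.frag_sd, size=n)
    return np.maximum(np.round(lens).astype(np.int64), 2 * cfg.min_seg + 80)


def _zip_family(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Zero-inflated Poisson read-pair family sizes, one strand."""
    if cfg.fixed_family_size is not None:
        return np.full(n, cfg.fixed_family_size, dtype=np.int64)
    lam = cfg.family_poisson_mean
    k = rng.poisson(lam, size=n)
    k[rng.random(n) < cfg.family_zero_inflation] = 0
    return k


def _families(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Per-molecule (strand0, strand1) families; at least one read pair in
    total (a molecule with no sequenced replicate is never observed)."""
    if cfg.collate_mode == "ligation":
        fam = np.stack([_zip_family(rng, n, cfg), _zip_family(rng, n, cfg)], axis=1)
        bad = fam.sum(axis=1) == 0
        while bad.any():
            m = int(bad.sum())
            fam[bad] = np.stack([_zip_family(rng, m, cfg), _zip_family(rng, m, cfg)], axis=1)
            bad = fam.sum(axis=1) == 0
    else:
        k = _zip_family(rng, n, cfg)
        bad = k == 0
        while bad.any():
            k[bad] = _zip_family(rng, int(bad.sum()), cfg)
            bad = k == 0
        side = rng.random(n) < 0.5
        fam = np.zeros((n, 2), dtype=np.int64)
        fam[side, 0] = k[side]
        fam[~side, 1] = k[~side]
    return fam


def simulate_library(genome: GenomeModel, targets: TargetRegionSet, plan: SimPlan,
                     cfg: SimConfig, sample: str = "S1",
                     sam_path: str = "sim.sam",
                     truth_pairs_path: str = "truth_pairs.tsv",
                     truth_junctions_path: str = "truth_junctions.tsv",
                     seed: Optional[int] = None) -> dict:
    """Draw capture-enriched fragments from the clone mixture, inject
    artifact molecules, replicate read-pair families per strand and emit
    aligned SAM records plus per-read-pair ground truth."""
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 202]))
    chroms = [name for name, _ in genome.chromosomes]
    seqs = {c: genome.fetch(c, 1, genome.chrom_length(c)) for c in chroms}
    regions = {r.chrom: r for r in targets}
    delta = cfg.depth / cfg.frag_mean

    # clone pools: (clone_index, fraction); -1 = SV-free background
    bg = 1.0 - sum(c.fraction for c in cfg.clones)
    pools = [(i, c.fraction) for i, c in enumerate(cfg.clones)]
    if bg > 1e-9:
        pools.append((-1, bg))

    overlays: dict[int, dict[str, list[tuple[int, str]]]] = {}
    for j in plan.sv_junctions:
        for flank, dist, chrom, pos, alt in j.snvs:
            overlays.setdefault(j.clone_index, {}).setdefault(chrom, []).append((pos, alt))

    ref_hap = {c: _ChromHap([("ref", 1, cfg.chrom_length)], [None]) for c in chroms}
    descs: list[_MolDesc] = []
    fid = 0
    for clone_index, fraction in pools:
        for hap in (0, 1):
            for chrom in chroms:
                model = ref_hap[chrom]
                overlay_pos: list[tuple[int, str]] = []
                if hap == 1 and clone_index >= 0:
                    model = _build_hap(cfg, plan, clone_index, chrom)
                    overlay_pos = sorted(overlays.get(clone_index, {}).get(chrom, []))
                n = rng.poisson(delta * model.total * fraction / 2)
                if n == 0:
                    continue
                starts = rng.integers(0, model.total, size=n)
                lens = _draw_frag_lengths(rng, n, cfg)
                ends = np.minimum(starts + lens, model.total)
                keep = ends - starts >= 2 * cfg.min_seg + 60
                starts, ends = starts[keep], ends[keep]
                # approximate reference coordinates for capture
                # classification (ref blocks dominate; offsets are small)
                ref_starts = starts
                r = regions[chrom]
                ref_ends = ref_starts + (ends - starts)
                is_t = (ref_starts <= r.end) & (ref_ends >= r.start)
                in_a = np.zeros(len(starts), dtype=bool)
                for a0, a1 in (r.left_a, r.right_a):
                    if a1 >= a0:
                        in_a |= (ref_starts <= a1) & (ref_ends >= a0)
                p = np.full(len(starts), cfg.capture_prob["-"])
                p[in_a] = cfg.capture_prob["A"]
                p[is_t] = cfg.capture_prob["T"]
                acc = rng.random(len(starts)) < p
                starts, ends = starts[acc], ends[acc]
                for s, e in zip(starts.tolist(), ends.tolist()):
                    fid += 1
                    if model.boundaries.size and model.crosses(s, e):
                        parts, jids = model.parts_for(chrom, s, e)
                        cls, jid = "trueSV", (jids[0] if jids else "")
                    else:
                        kind, rpos = model.ref_pos(s)
                        if kind is None:
                            continue
                        parts = [("ref", chrom, rpos, rpos + (e - s) - 1, "+")]
                        cls, jid = "proper", ""
                    ov = None
                    if overlay_pos:
                        hit = [(chrom, int(x), a) for x, a in overlay_pos
                               if any(pp[0] == "ref" and pp[2] <= x <= pp[3]
                                      for pp in parts)]
                        ov = hit or None
                    descs.append(_MolDesc(fid=fid, parts=parts, cls=cls, jid=jid,
                                          fam=(0, 0), mapq=60, umi=None, overlay=ov))

    n_accepted = len(descs)

    # ---- artifact molecules -----------------------------------------
    def frag_len() -> int:
        return int(_draw_frag_lengths(rng, 1, cfg)[0])

    def flank_piece(node: JunctionNode, length: int, upstream: bool) -> tuple:
        if upstream:   # piece ends at the node, read toward the junction
            if node.side == "L":
                return ("ref", node.chrom, node.pos - length + 1, node.pos, "+")
            return ("ref", node.chrom, node.pos, node.pos + length - 1, "-")
        if node.side == "R":
            return ("ref", node.chrom, node.pos, node.pos + length - 1, "+")
        return ("ref", node.chrom, node.pos - length + 1, node.pos, "-")

    used_junctions: list[PlannedJunction] = [j for j in plan.sv_junctions]

    if cfg.ligation_chimera_rate > 0 and plan.ligation_sites:
        n_lig = min(rng.binomial(n_accepted, cfg.ligation_chimera_rate),
                    len(plan.ligation_sites))
        for site in plan.ligation_sites[:n_lig]:
            fid += 1
            la, lb = frag_len(), frag_len()
            parts = [flank_piece(site.node_a, la, True)]
            if site.insert_seq:
                parts.append(("ins", site.insert_seq))
            parts.append(flank_piece(site.node_b, lb, False))
            descs.append(_MolDesc(fid=fid, parts=parts, cls="ligation",
                                  jid=site.jid, fam=(0, 0), mapq=60, umi=None))
            used_junctions.append(site)

    chim_descs: list[_MolDesc] = []
    if cfg.chimeric_pcr_rate > 0 and plan.chimera_sites:
        n_chim = min(rng.binomial(n_accepted, cfg.chimeric_pcr_rate),
                     len(plan.chimera_sites))
        for site in plan.chimera_sites[:n_chim]:
            f = frag_len()
            la = max(cfg.min_seg + 20, int(f * rng.uniform(0.35, 0.65)))
            lb = max(cfg.min_seg + 20, f - la)
            partner_len = max(frag_len(), la + 40)
            # the chimera recombines a proper template: emit that template
            # too, sharing the chimera's upstream outer endpoint
            pa = site.node_a
            if pa.side == "L":
                partner = ("ref", pa.chrom, pa.pos - la + 1,
                           pa.pos - la + partner_len, "+")
            else:
                partner = ("ref", pa.chrom, pa.pos + la - partner_len,
                           pa.pos + la - 1, "-")
            fid += 1
            descs.append(_MolDesc(fid=fid, parts=[partner], cls="proper", jid="",
                                  fam=(0, 0), mapq=60, umi=None))
            fid += 1
            chim = _MolDesc(fid=fid,
                            parts=[flank_piece(pa, la, True),
                                   flank_piece(site.node_b, lb, False)],
                            cls="chimericPCR", jid=site.jid,
                            fam=(1, 0) if rng.random() < 0.5 else (0, 1),
                            mapq=60, umi=None)
            chim_descs.append(chim)
            used_junctions.append(site)

    if cfg.mode == "tagmentation" and cfg.foldback_rate > 0 and plan.foldback_sites:
        n_fb = min(rng.binomial(n_accepted, cfg.foldback_rate),
                   len(plan.foldback_sites))
        for site in plan.foldback_sites[:n_fb]:
            fid += 1
            f = frag_len()
            la = max(cfg.min_seg + 20, int(f * rng.uniform(0.4, 0.6)))
            lb = max(cfg.min_seg + 20, f - la)
            descs.append(_MolDesc(fid=fid,
                                  parts=[flank_piece(site.node_a, la, True),
                                         flank_piece(site.node_b, lb, False)],
                                  cls="foldback", jid=site.jid,
                                  fam=(0, 0), mapq=60, umi=None))
            used_junctions.append(site)

    # ---- family sizes, UMIs, MAPQ -----------------------------------
    fam = _families(rng, len(descs), cfg)
    if cfg.low_mapq_fraction > 0:
        low = rng.random(len(descs)) < cfg.low_mapq_fraction
    else:
        low = np.zeros(len(descs), dtype=bool)
    is_ligation_lib = cfg.collate_mode == "ligation"
    umi_idx = rng.integers(1, cfg.umi_count + 1, size=(len(descs), 2)) \
        if is_ligation_lib else None
    for i, d in enumerate(descs):
        d.fam = (int(fam[i, 0]), int(fam[i, 1]))
        if low[i]:
            d.mapq = cfg.low_mapq_value
        if is_ligation_lib:
            d.umi = (int(umi_idx[i, 0]), int(umi_idx[i, 1]))
    if is_ligation_lib:
        for d in chim_descs:
            d.umi = (int(rng.integers(1, cfg.umi_count + 1)),
                     int(rng.integers(1, cfg.umi_count + 1)))
    descs.extend(chim_descs)

    # ---- emission ----------------------------------------------------
    sam = _SamWriter(sam_path, genome)
    truth: list[str] = []
    umi_seqs = plan.umis if is_ligation_lib else None
    stats = {"proper": 0, "trueSV": 0, "ligation": 0, "chimericPCR": 0,
             "foldback": 0, "read_pairs": 0}
    with open(truth_pairs_path, "w") as tf:
        tf.write("qname\tsample\tfragment\tclass\tjid\tstrand\trep\t"
                 "chrom1\touter1\tside1\tchrom2\touter2\tside2\tn_parts\n")
        for d in descs:
            stats[d.cls] += 1
            stats["read_pairs"] += d.fam[0] + d.fam[1]
            _emit_molecule(sam, truth, d, cfg, rng, seqs, sample, umi_seqs)
            if len(truth) >= 50_000:
                tf.write("\n".join(truth) + "\n")
                truth = []
        if truth:
            tf.write("\n".join(truth) + "\n")
    sam.close()

    chrom_order = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
    with open(truth_junctions_path, "w") as jf:
        jf.write("jid\tkind\tclone\tsv_type\tchrom1\tpos1\tside1\t"
                 "chrom2\tpos2\tside2\tmetric\tinsert\tsnvs\n")
        for j in used_junctions:
            n1, n2 = j.canonical_nodes(chrom_order)
            snv_txt = ";".join(f"{f}:{dd}:{c}:{p}:{a}" for f, dd, c, p, a in j.snvs)
            jf.write(f"{j.jid}\t{j.kind}\t{j.clone_index}\t{j.sv_type or j.kind}\t"
                     f"{n1.chrom}\t{n1.pos}\t{n1.side}\t{n2.chrom}\t{n2.pos}\t"
                     f"{n2.side}\t{j.metric}\t{j.insert_seq}\t{snv_txt}\n")
    return stats


def simulate_run(cfg: SimConfig, outdir: str,
                 samples: tuple[str, ...] = ("S1",)) -> dict:
    """Full simulation: genome + targets + per-sample libraries, written
    as FASTA/BED/SAM/TSV under `outdir`.  Identical SimConfig (including
    seed) yields byte-identical outputs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome, targets, plan = make_genome(cfg)
    fasta = out / "ref.fa"
    bed = out / "targets.bed"
    genome.write_fasta(str(fasta))
    targets.write_bed(str(bed))
    (out / "umis.txt").write_text("\n".join(plan.umis) + "\n")
    result = {"fasta": str(fasta), "bed": str(bed), "umis": str(out / "umis.txt"),
              "samples": {}, "genome": genome, "targets": targets, "plan": plan}
    for si, sample in enumerate(samples):
        sam_path = out / f"{sample}.sam"
        tp = out / f"{sample}.truth_pairs.tsv"
        tj = out / f"{sample}.truth_junctions.tsv"
        stats = simulate_library(
            genome, targets, plan, cfg, sample=sample,
            sam_path=str(sam_path), truth_pairs_path=str(tp),
            truth_junctions_path=str(tj),
            seed=(cfg.seed * 1000 + 7 * si) & 0x7FFFFFFF)
        result["samples"][sample] = {
            "sam": str(sam_path), "truth_pairs": str(tp),
            "truth_junctions": str(tj), "stats": stats}
    try:
        import yaml
        cfg_dict = asdict(cfg)
        (out / "sim_config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    except Exception:
        pass
    return result
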