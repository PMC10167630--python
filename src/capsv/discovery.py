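"""Cross-molecule SV assembly: cluster per-molecule junction candidates
into SV calls (optionally across co-analyzed samples), purge near-duplicate
source molecules, recover outer-clipped support, reconstruct gap-only
junctions and characterize the junction (microhomology / de novo insertion,
cross-molecule junction consensus, capture target class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .junction import JunctionCandidate, JunctionNode, sv_type_of
from .molecule import N_CODE, SourceMolecule
from .seqio import GenomeModel, TargetRegionSet, revcomp

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


@dataclass(slots=True)
class Supporter:
    molecule: SourceMolecule
    evidence: str                       # 'split' | 'gap' | 'outer_clip'
    candidate: Optional[JunctionCandidate] = None


@dataclass
class SVCall:
    id: str
    node1: JunctionNode
    node2: JunctionNode
    sv_type: str
    imprecise: bool
    supporters: list[Supporter]
    reference_molecule: Optional[str] = None
    junction_metric: Optional[int] = None
    insert_sequence: str = ""
    mh_left: int = 0                    # microhomology bases on each flank side
    mh_right: int = 0
    junction_consensus: str = ""
    flank_columns: list[tuple] = field(default_factory=list)
    target_class: str = "--"
    vaf_by_sample: dict[str, float] = field(default_factory=dict)
    vaf: Optional[float] = None

    # -- aggregates ---------------------------------------------------
    @property
    def size(self) -> Optional[int]:
        if self.node1.chrom != self.node2.chrom:
            return None
        return abs(self.node2.pos - self.node1.pos)

    @property
    def n_molecules(self) -> int:
        return len({s.molecule.id for s in self.supporters})

    @property
    def n_duplex(self) -> int:
        return len({s.molecule.id for s in self.supporters if s.molecule.is_duplex})

    @property
    def n_read_pairs(self) -> int:
        return sum(s.molecule.n_read_pairs for s in self.supporters)

    @property
    def n_outer_clips(self) -> int:
        return sum(1 for s in self.supporters if s.evidence == "outer_clip")

    @property
    def max_family_size(self) -> int:
        return max((max(s.molecule.strand_family) for s in self.supporters), default=0)

    @property
    def max_molecule_read_pairs(self) -> int:
        return max((s.molecule.n_read_pairs for s in self.supporters), default=0)

    @property
    def shared_endpoint_count(self) -> int:
        return sum(1 for s in self.supporters if s.molecule.shared_outer)

    @property
    def samples(self) -> set[str]:
        return {s.molecule.sample for s in self.supporters}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def best_flank_mapq(self) -> int:
        vals = [s.candidate.min_flank_mapq for s in self.supporters if s.candidate]
        return max(vals) if vals else 60

    def supporters_in(self, sample: str) -> list[Supporter]:
        return [s for s in self.supporters if s.molecule.sample == sample]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _blocks(cands: list[JunctionCandidate], which: int, max_gap: int,
            chrom_order: dict[str, int]) -> Iterable[list[JunctionCandidate]]:
    key = (lambda c: c.node1.sort_key(chrom_order)) if which == 1 \
        else (lambda c: c.node2.sort_key(chrom_order))
    cands = sorted(cands, key=key)
    block: list[JunctionCandidate] = []
    prev = None
    for c in cands:
        k = key(c)
        if prev is not None and (k[0] != prev[0] or k[2] != prev[2]
                                 or k[1] - prev[1] >= max_gap):
            yield block
            block = []
        block.append(c)
        prev = k
    if block:
        yield block


def _gap_compatible(gap: JunctionCandidate, n1: JunctionNode, n2: JunctionNode,
                    max_gap: int, mh_slop: int = 20) -> Optional[int]:
    """Distance score when a gap candidate's inner read ends are consistent
    with a precise junction (junction lies beyond each inner end, in the
    direction opposite the node side), else None.  `mh_slop` absorbs
    alignment extension through junction microhomology, which can place a
    read end slightly past the called breakpoint."""
    total = 0
    for gn, pn in ((gap.node1, n1), (gap.node2, n2)):
        if gn.chrom != pn.chrom or gn.side != pn.side:
            return None
        d = pn.pos - gn.pos if gn.side == "L" else gn.pos - pn.pos
        if d < -mh_slop or d > max_gap:
            return None
        total += abs(d)
    return total


def reconstruct_gap_junctions(gaps: list[JunctionCandidate]
                              ) -> tuple[JunctionNode, JunctionNode]:
    """Nominal breakpoints of a gap-only junction: the innermost aligned
    read ends over its supporters (max position for L-side nodes, min for
    R-side)."""
    def innermost(nodes: list[JunctionNode]) -> JunctionNode:
        side = nodes[0].side
        pos = max(n.pos for n in nodes) if side == "L" else min(n.pos for n in nodes)
        return JunctionNode(nodes[0].chrom, pos, side)

    return (innermost([g.node1 for g in gaps]), innermost([g.node2 for g in gaps]))


def find_sv_sets(candidates: list[JunctionCandidate], max_proper_insert: int,
                 chrom_order: dict[str, int] | None = None) -> list[SVCall]:
    """Two-pass clustering of canonically sorted candidate node pairs:
    sort by left node, break into sets where consecutive left nodes are
    separated by at least the maximum proper insert size, re-sort each set
    by the right node and repeat.  Candidates from all co-analyzed samples
    are clustered together so that even single source molecules match
    between samples."""
    chrom_order = chrom_order or {}
    calls: list[SVCall] = []
    for block1 in _blocks(candidates, 1, max_proper_insert, chrom_order):
        for block in _blocks(block1, 2, max_proper_insert, chrom_order):
            splits = [c for c in block if c.evidence == "split"]
            gaps = [c for c in block if c.evidence == "gap"]
            precise: dict[tuple, list[JunctionCandidate]] = {}
            for c in splits:
                precise.setdefault((c.node1, c.node2, c.insert_len), []).append(c)
            assigned: dict[int, list[JunctionCandidate]] = {i: [] for i in range(len(precise))}
            keys = sorted(precise.keys(),
                          key=lambda k: (k[0].sort_key(chrom_order),
                                         k[1].sort_key(chrom_order), k[2]))
            leftover: list[JunctionCandidate] = []
            for g in gaps:
                best, best_d = None, None
                for i, k in enumerate(keys):
                    d = _gap_compatible(g, k[0], k[1], max_proper_insert)
                    if d is not None and (best_d is None or d < best_d):
                        best, best_d = i, d
                if best is not None:
                    assigned[best].append(g)
                else:
                    leftover.append(g)
            for i, k in enumerate(keys):
                members = precise[k] + assigned[i]
                calls.append(_make_call(k[0], k[1], members, imprecise=False))
            if leftover:
                n1, n2 = reconstruct_gap_junctions(leftover)
                calls.append(_make_call(n1, n2, leftover, imprecise=True))
    for i, call in enumerate(calls):
        call.id = f"sv{i + 1}"
    return calls


def _make_call(n1: JunctionNode, n2: JunctionNode,
               members: list[JunctionCandidate], imprecise: bool) -> SVCall:
    seen: set[str] = set()
    supporters = []
    for c in members:
        if c.molecule.id in seen:
            continue
        seen.add(c.molecule.id)
        supporters.append(Supporter(c.molecule, c.evidence, c))
    return SVCall(id="", node1=n1, node2=n2, sv_type=sv_type_of(n1, n2),
                  imprecise=imprecise, supporters=supporters)


# ---------------------------------------------------------------------------
# Duplicate purging and outer-clip recovery
# ---------------------------------------------------------------------------

def purge_near_duplicates(sv: SVCall, total_allowance: int = 5) -> SVCall:
    """Within one sample, purge likely duplicate source molecules whose
    outer endpoints are closer than `total_allowance` bases in total
    (summed over both endpoints); the lower-family-size molecule is
    removed.  Strict inequality on the sum."""
    by_sample: dict[str, list[Supporter]] = {}
    for s in sv.supporters:
        if s.evidence == "outer_clip":
            continue
        by_sample.setdefault(s.molecule.sample, []).append(s)
    removed: set[str] = set()
    for sample, sups in by_sample.items():
        sups = sorted(sups, key=lambda s: (-s.molecule.n_read_pairs, s.molecule.id))
        kept: list[Supporter] = []
        for s in sups:
            k = s.molecule.key
            dup = False
            for other in kept:
                ok = other.molecule.key
                if (k.end1[0] == ok.end1[0] and k.end2[0] == ok.end2[0]
                        and k.end1[2] == ok.end1[2] and k.end2[2] == ok.end2[2]):
                    dist = abs(k.end1[1] - ok.end1[1]) + abs(k.end2[1] - ok.end2[1])
                    if dist < total_allowance:
                        dup = True
                        break
            if dup:
                removed.add(s.molecule.id)
            else:
                kept.append(s)
    if removed:
        sv.supporters = [s for s in sv.supporters if s.molecule.id not in removed]
    return sv


def flank_from_junction(genome: GenomeModel, node: JunctionNode, n: int) -> str:
    """First n reference bases of a junction flank, reading away from the
    junction in molecule orientation, starting at the node position."""
    if node.side == "R":
        end = min(node.pos + n - 1, genome.chrom_length(node.chrom))
        return genome.fetch(node.chrom, node.pos, end)
    start = max(node.pos - n + 1, 1)
    return revcomp(genome.fetch(node.chrom, start, node.pos))


def flank_into_junction(genome: GenomeModel, node: JunctionNode, n: int) -> str:
    """Last n reference bases of a flank reading toward the junction in
    molecule orientation, ending at the node position."""
    if node.side == "L":
        start = max(node.pos - n + 1, 1)
        return genome.fetch(node.chrom, start, node.pos)
    end = min(node.pos + n - 1, genome.chrom_length(node.chrom))
    return revcomp(genome.fetch(node.chrom, node.pos, end))


def _move_along_flank(node: JunctionNode, delta: int, upstream: bool) -> JunctionNode:
    """Shift a node along its flank's molecule orientation.  For the
    upstream (first) flank molecule direction increases toward the
    junction; for the downstream flank it increases away from it."""
    if upstream:
        sign = 1 if node.side == "L" else -1
    else:
        sign = 1 if node.side == "R" else -1
    return JunctionNode(node.chrom, node.pos + sign * delta, node.side)


def recover_outer_clips(proper_molecules: Iterable[SourceMolecule],
                        svs: list[SVCall], genome: GenomeModel,
                        min_clip: int = 5, max_check: int = 20) -> list[SVCall]:
    """Recover source molecules clipped at an SV junction on their outer
    edge by at least `min_clip` bases: the molecule's outer endpoint must
    coincide with an SV inner node and the clipped bases must match the
    SV's far-side flank (exact match of min(clip, max_check) bases).

    Junction microhomology shifts alignment endpoints: a clipped molecule
    whose aligned part lies on the upstream flank ends at the called
    (upstream-maximal) breakpoint, whereas one lying on the downstream
    flank starts at the opposite placement extreme, `metric` bases back
    along both flanks.  Both placements are probed, and for insertion
    junctions the inserted bases precede the far flank in the clip.
    """
    # index entries: key node -> (sv, far node, insert-first?) per placement
    index: dict[tuple[str, int, str], list[tuple[SVCall, JunctionNode, bool]]] = {}
    for sv in svs:
        if sv.imprecise or sv.junction_metric is None:
            continue
        m = max(sv.junction_metric, 0)
        n1_lo = _move_along_flank(sv.node1, -m, upstream=True)
        n2_lo = _move_along_flank(sv.node2, -m, upstream=False)
        # upstream-flank molecules: clipped at the called node1, continue into flank 2
        index.setdefault((sv.node1.chrom, sv.node1.pos, sv.node1.side),
                         []).append((sv, sv.node2, True))
        # downstream-flank molecules: clipped at the low-placement node2
        index.setdefault((n2_lo.chrom, n2_lo.pos, n2_lo.side),
                         []).append((sv, n1_lo, False))
    if not index:
        return svs
    for mol in proper_molecules:
        entry, exit_ = mol.outer_nodes()
        for node, clip_seq, is_entry in (
                (entry, mol.entry_clip_seq, True),
                (exit_, mol.exit_clip_seq, False)):
            if len(clip_seq) < min_clip:
                continue
            hits = index.get(node)
            if not hits:
                continue
            n = min(len(clip_seq), max_check)
            for sv, other, upstream_key in hits:
                # clip continuation in the clipped molecule's own (fragment)
                # orientation; the de novo insert reads forward when that
                # orientation agrees with the SV-canonical one
                forward = upstream_key != is_entry
                ins = sv.insert_sequence if forward else revcomp(sv.insert_sequence)
                if is_entry:
                    ext = flank_into_junction(genome, other, n)
                    expected = (ext + ins)[-n:]
                    observed = clip_seq[-n:]
                else:
                    ext = flank_from_junction(genome, other, n)
                    expected = (ins + ext)[:n]
                    observed = clip_seq[:n]
                if observed == expected:
                    if mol.id not in {s.molecule.id for s in sv.supporters}:
                        sv.supporters.append(Supporter(mol, "outer_clip"))
    return svs


# ---------------------------------------------------------------------------
# Junction characterization
# ---------------------------------------------------------------------------

def _oriented_base(genome: GenomeModel, chrom: str, pos: int, forward: bool) -> str:
    if pos < 1 or pos > genome.chrom_length(chrom):
        return "?"
    b = genome.base(chrom, pos)
    return b if forward else _COMP1.get(b, "N")


def _flank_base(genome: GenomeModel, node: JunctionNode, offset: int) -> str:
    """Base at `offset` molecule-oriented positions from the node position
    (offset 0 = the node base; negative = toward/past the junction tail,
    positive = away).  For side L flanks molecule orientation is the
    reference forward strand going left-to-right up to pos; for side R it
    is the reverse complement going right-to-left."""
    if node.side == "L":
        return _oriented_base(genome, node.chrom, node.pos + offset, True)
    return _oriented_base(genome, node.chrom, node.pos - offset, False)


def junction_homology(genome: GenomeModel, node1: JunctionNode,
                      node2: JunctionNode, max_k: int = 200) -> tuple[int, int]:
    """Microhomology extension (left, right) at a precise junction: the
    number of alternative breakpoint placements shifting the junction
    toward the first (left) or second (right) flank that produce the same
    molecule sequence."""
    # node1 is the junction's upstream flank in molecule orientation when
    # its side is L; otherwise orientations are handled by _flank_base.
    # Left flank A reads ...b(-1) b(0) | junction | then flank B.
    def a_before(j):   # j-th base before the junction on flank A (j>=1)
        return _flank_base(genome, node1, -(j - 1)) if node1.side == "L" \
            else _oriented_base(genome, node1.chrom, node1.pos + (j - 1), False)

    def b_ext_before(j):  # reference of flank B extended j bases before the junction
        if node2.side == "R":
            return _oriented_base(genome, node2.chrom, node2.pos - j, True)
        return _oriented_base(genome, node2.chrom, node2.pos + j, False)

    def a_ext_after(j):  # reference of flank A extended j bases past the junction
        if node1.side == "L":
            return _oriented_base(genome, node1.chrom, node1.pos + j, True)
        return _oriented_base(genome, node1.chrom, node1.pos - j, False)

    def b_after(j):    # j-th base after the junction on flank B (j>=1)
        if node2.side == "R":
            return _oriented_base(genome, node2.chrom, node2.pos + (j - 1), True)
        return _oriented_base(genome, node2.chrom, node2.pos - (j - 1), False)

    k_left = 0
    while k_left < max_k:
        a, b = a_before(k_left + 1), b_ext_before(k_left + 1)
        if a == "?" or b == "?" or a != b:
            break
        k_left += 1
    k_right = 0
    while k_right < max_k:
        a, b = a_ext_after(k_right + 1), b_after(k_right + 1)
        if a == "?" or b == "?" or a != b:
            break
        k_right += 1
    return k_left, k_right


def _consensus_base_at(mol: SourceMolecule, chrom: str, pos: int) -> Optional[str]:
    for c, s, arr in mol.effective_consensus():
        if c == chrom and s <= pos < s + len(arr):
            return chr(arr[pos - s])
    return None


def _junction_query_centrality(cand: JunctionCandidate) -> float:
    """Distance of the junction from the midpoint of the molecule's
    sequenced span, used to pick the reference molecule."""
    path = cand.molecule.path
    lengths = [seg.end - seg.start + 1 for seg in path.segs]
    total = sum(lengths) + sum(m.insert_len for m in path.markers)
    qpos = sum(lengths[:cand.marker_index + 1])
    qpos += sum(m.insert_len for m in path.markers[:cand.marker_index])
    return abs(qpos - total / 2)


def characterize_junction(sv: SVCall, genome: GenomeModel,
                          window: int = 150, threshold: float = 2 / 3) -> SVCall:
    """Choose the reference molecule (most central junction), compute the
    signed junction metric (microhomology > 0, 0 blunt, de novo insertion
    < 0) and build the cross-molecule junction consensus with per-column
    flank coordinates."""
    splits = [s for s in sv.supporters if s.evidence == "split" and s.candidate]
    if not splits or sv.imprecise:
        sv.junction_metric = None
        return sv
    ref_sup = min(splits, key=lambda s: (
        _junction_query_centrality(s.candidate),
        -s.molecule.n_read_pairs, s.molecule.id))
    sv.reference_molecule = ref_sup.molecule.id
    cand = ref_sup.candidate
    if cand.insert_len > 0:
        sv.junction_metric = -cand.insert_len
        sv.insert_sequence = cand.insert_seq
        sv.mh_left = sv.mh_right = 0
    else:
        k_left, k_right = junction_homology(genome, sv.node1, sv.node2)
        sv.junction_metric = k_left + k_right
        sv.mh_left, sv.mh_right = k_left, k_right

    # cross-molecule junction consensus over +-window flank columns
    mols = [s.molecule for s in sv.supporters if s.evidence != "outer_clip"]
    cols: list[tuple] = []
    left_seq: list[str] = []
    for j in range(window, 0, -1):
        chrom = sv.node1.chrom
        pos = sv.node1.pos - (j - 1) if sv.node1.side == "L" else sv.node1.pos + (j - 1)
        base = _vote_column(mols, chrom, pos, threshold)
        if base is None:
            continue
        cols.append(("left", j, chrom, pos, base))
        left_seq.append(base if sv.node1.side == "L" else _COMP1.get(base, "N"))
    right_seq: list[str] = []
    for j in range(1, window + 1):
        chrom = sv.node2.chrom
        pos = sv.node2.pos + (j - 1) if sv.node2.side == "R" else sv.node2.pos - (j - 1)
        base = _vote_column(mols, chrom, pos, threshold)
        if base is None:
            continue
        cols.append(("right", j, chrom, pos, base))
        right_seq.append(base if sv.node2.side == "R" else _COMP1.get(base, "N"))
    sv.flank_columns = cols
    sv.junction_consensus = "".join(left_seq) + sv.insert_sequence + "".join(right_seq)
    return sv


def _vote_column(mols: list[SourceMolecule], chrom: str, pos: int,
                 threshold: float) -> Optional[str]:
    votes: dict[str, int] = {}
    for mol in mols:
        b = _consensus_base_at(mol, chrom, pos)
        if b is None or b == "N":
            continue
        votes[b] = votes.get(b, 0) + 1
    if not votes:
        return None
    total = sum(votes.values())
    base, n = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
    return base if n + 1e-9 >= threshold * total else "N"


def classify_sv(sv: SVCall, targets: TargetRegionSet) -> str:
    """Two-character capture target class: uppercase when both breakends
    fall in the same target locus (its T span or A flanks), lowercase for
    all other, often artifactual, combinations."""
    c1, l1 = targets.classify_point(sv.node1.chrom, sv.node1.pos)
    c2, l2 = targets.classify_point(sv.node2.chrom, sv.node2.pos)
    same_locus = l1 is not None and l1 == l2
    code = c1 + c2
    sv.target_class = code.upper() if same_locus else code.lower()
    return sv.target_class


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def discover(candidates: list[JunctionCandidate],
             proper_molecules: list[SourceMolecule],
             genome: GenomeModel, targets: TargetRegionSet | None,
             max_proper_insert: int,
             purge_allowance: int = 5, min_clip: int = 5,
             characterize_window: int = 150) -> list[SVCall]:
    """find -> purge duplicates -> recover outer clips -> characterize ->
    classify, returning unfiltered SV calls."""
    chrom_order = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
    svs = find_sv_sets(candidates, max_proper_insert, chrom_order)
    for sv in svs:
        purge_near_duplicates(sv, purge_allowance)
    svs = [sv for sv in svs if sv.supporters]
    for sv in svs:
        characterize_junction(sv, genome, window=characterize_window)
    # characterization precedes clip recovery: the junction metric defines
    # the placement extremes probed for clipped molecule endpoints
    recover_outer_clips(proper_molecules, svs, genome, min_clip=min_clip)
    for sv in svs:
        if targets is not None:
            classify_sv(sv, targets)
    return svs
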