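"""Per-molecule junction analysis: convert each source molecule into
junction nodes, detect SV junction candidates (split and gap evidence) and
flag molecules that share outer endpoints with properly paired molecules
(the chimeric-PCR signature: artifact templates pre-exist in the library).

A node is (chromosome, position, side) where side is the direction (L/R)
the molecule proceeds from that position along the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .molecule import SourceMolecule, MoleculePath
from .seqio import GenomeModel


@dataclass(frozen=True, slots=True, order=False)
class JunctionNode:
    chrom: str
    pos: int
    side: str   # 'L' or 'R'

    def sort_key(self, chrom_order: dict[str, int]):
        return (chrom_order.get(self.chrom, 1 << 30), self.pos, self.side)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.side}"


def sv_type_of(n1: JunctionNode, n2: JunctionNode) -> str:
    """Canonical breakend-to-type mapping for a sorted node pair."""
    if n1.chrom != n2.chrom:
        return "Trans"
    if n1.side == n2.side:
        return "Inv"
    return "Del" if n1.side == "L" else "Dup"


@dataclass(slots=True)
class JunctionCandidate:
    molecule: SourceMolecule
    node1: JunctionNode          # canonically sorted
    node2: JunctionNode
    evidence: str                # 'split' | 'gap'
    sv_type: str
    insert_len: int = 0
    insert_seq: str = ""
    flank_mapqs: tuple[int, int] = (0, 0)
    imprecise: bool = False
    shared_outer_endpoint: bool = False
    marker_index: int = 0

    @property
    def min_flank_mapq(self) -> int:
        return min(self.flank_mapqs)


def _canonical_pair(a: JunctionNode, b: JunctionNode,
                    chrom_order: dict[str, int]) -> tuple[JunctionNode, JunctionNode]:
    if a.sort_key(chrom_order) <= b.sort_key(chrom_order):
        return a, b
    return b, a


def extract_nodes(mol: SourceMolecule
                  ) -> tuple[tuple[JunctionNode, JunctionNode],
                             list[tuple[JunctionNode, JunctionNode]]]:
    """Outer node pair and the list of inner node pairs (one per junction
    between consecutive alignment segments of the molecule path)."""
    path = mol.path
    outer = (JunctionNode(*path.entry_node()), JunctionNode(*path.exit_node()))
    inner: list[tuple[JunctionNode, JunctionNode]] = []
    for i in range(len(path.segs) - 1):
        prev, nxt = path.segs[i], path.segs[i + 1]
        exit_node = (JunctionNode(prev.chrom, prev.end, "L") if prev.frag_strand == "+"
                     else JunctionNode(prev.chrom, prev.start, "R"))
        entry_node = (JunctionNode(nxt.chrom, nxt.start, "R") if nxt.frag_strand == "+"
                      else JunctionNode(nxt.chrom, nxt.end, "L"))
        inner.append((exit_node, entry_node))
    return outer, inner


def _pair_is_concordant(path: MoleculePath, i: int, max_proper_insert: int) -> bool:
    """Concordance of the two mates around the unsequenced pair gap at
    marker i: same chromosome and fragment orientation, forward order, and
    an implied insert within the proper limit.

    For a simple two-segment molecule the implied insert is the outer
    span; when the molecule already carries split junction evidence the
    span is inflated by the sequenced junction itself, so the unsequenced
    gap between the flanking segments is judged locally instead."""
    prev, nxt = path.segs[i], path.segs[i + 1]
    if prev.chrom != nxt.chrom or prev.frag_strand != nxt.frag_strand:
        return False
    if prev.frag_strand == "+":
        if nxt.start < prev.start:
            return False
        local_gap = nxt.start - prev.end - 1
    else:
        if nxt.end > prev.end:
            return False
        local_gap = prev.start - nxt.end - 1
    if any(m.kind == "split" for m in path.markers):
        return -20 <= local_gap <= max_proper_insert
    e1, e2 = path.entry_node(), path.exit_node()
    span = abs(e2[1] - e1[1]) + 1
    return span <= max_proper_insert


def call_candidates(mol: SourceMolecule, genome: GenomeModel | None,
                    min_sv_size: int = 50,
                    max_proper_insert: int = 1000,
                    chrom_order: dict[str, int] | None = None,
                    ) -> list[JunctionCandidate]:
    """Examine a molecule's alignment path for patterns predicting an SV
    junction; sets mol.mol_class as a side effect."""
    chrom_order = chrom_order or {}
    path = mol.path
    out: list[JunctionCandidate] = []
    _, inner = extract_nodes(mol)
    has_split = False
    has_gap = False
    for i, marker in enumerate(path.markers):
        exit_node, entry_node = inner[i]
        if marker.kind == "split":
            if (exit_node.chrom == entry_node.chrom
                    and exit_node.side != entry_node.side
                    and abs(entry_node.pos - exit_node.pos) < min_sv_size
                    and marker.insert_len < min_sv_size):
                continue  # small indel, not an SV junction
            if (exit_node.chrom == entry_node.chrom
                    and exit_node.side == entry_node.side
                    and abs(entry_node.pos - exit_node.pos) < min_sv_size):
                continue
            n1, n2 = _canonical_pair(exit_node, entry_node, chrom_order)
            out.append(JunctionCandidate(
                molecule=mol, node1=n1, node2=n2, evidence="split",
                sv_type=sv_type_of(n1, n2),
                insert_len=marker.insert_len, insert_seq=marker.insert_seq,
                flank_mapqs=(path.segs[i].mapq, path.segs[i + 1].mapq),
                marker_index=i))
            has_split = True
        else:  # pair boundary
            if _pair_is_concordant(path, i, max_proper_insert):
                continue
            n1, n2 = _canonical_pair(exit_node, entry_node, chrom_order)
            out.append(JunctionCandidate(
                molecule=mol, node1=n1, node2=n2, evidence="gap",
                sv_type=sv_type_of(n1, n2),
                flank_mapqs=(path.segs[i].mapq, path.segs[i + 1].mapq),
                imprecise=True, marker_index=i))
            has_gap = True
    mol.mol_class = ("sv_candidate" if has_split
                     else "gap_candidate" if has_gap else "proper")
    return out


def build_proper_endpoint_index(proper_molecules: Iterable[SourceMolecule]
                                ) -> dict[str, set[tuple[str, int, str]]]:
    """Per-sample index of the outer nodes of properly paired molecules."""
    index: dict[str, set[tuple[str, int, str]]] = {}
    for mol in proper_molecules:
        s = index.setdefault(mol.sample, set())
        for node in mol.outer_nodes():
            s.add(node)
    return index


def flag_shared_endpoints(candidates: list[JunctionCandidate],
                          proper_index: dict[str, set[tuple[str, int, str]]],
                          allowance: int = 1) -> list[JunctionCandidate]:
    """Flag candidates whose molecule shares an outer endpoint with a
    properly paired molecule of the same library — evidence that the SV
    molecule is a PCR artifact recombining pre-existing templates."""
    for cand in candidates:
        idx = proper_index.get(cand.molecule.sample)
        if not idx:
            continue
        hit = False
        for chrom, pos, side in cand.molecule.outer_nodes():
            for dp in range(-allowance, allowance + 1):
                if (chrom, pos + dp, side) in idx:
                    hit = True
                    break
            if hit:
                break
        cand.shared_outer_endpoint = hit
        cand.molecule.shared_outer = hit
    return candidates
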