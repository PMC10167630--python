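"""Shared test utilities: hand-built alignment groups, independent
brute-force oracles and truth matching for simulator-based tests."""

from __future__ import annotations

import itertools

from capsv.junction import JunctionNode
from capsv.seqio import AlignedSegment, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def make_pair(qname, chrom, start, end, *, sample="S", strand="+", mapq=60,
              read_len=75, umi=None, seq_by_pos=None, clip_left=0,
              clip_right=0, clip_left_seq="", clip_right_seq=""):
    """A simple concordant FR read pair over [start, end] (1-based),
    optionally with outer soft clips.  `strand` is the fragment top-strand
    orientation ('-' swaps which mate starts at which end)."""
    span = end - start + 1
    rl = min(read_len, span)

    def base_at(pos):
        if seq_by_pos is not None:
            return seq_by_pos(pos)
        return "ACGT"[pos % 4]

    r1_ref = "".join(base_at(p) for p in range(start, start + rl))
    r2_ref = "".join(base_at(p) for p in range(end - rl + 1, end + 1))
    if strand == "+":
        r1 = AlignedSegment(
            qname=qname, sample=sample, chrom=chrom, pos=start, strand="+",
            cigar=([("S", clip_left)] if clip_left else []) + [("M", rl)],
            mapq=mapq, seq=clip_left_seq + r1_ref, qual=None,
            is_supplementary=False, is_read2=False, is_merged=False, umi_raw=umi)
        r2 = AlignedSegment(
            qname=qname, sample=sample, chrom=chrom, pos=end - rl + 1, strand="-",
            cigar=[("M", rl)] + ([("S", clip_right)] if clip_right else []),
            mapq=mapq, seq=r2_ref + clip_right_seq, qual=None,
            is_supplementary=False, is_read2=True, is_merged=False, umi_raw=umi)
    else:
        r1 = AlignedSegment(
            qname=qname, sample=sample, chrom=chrom, pos=end - rl + 1, strand="-",
            cigar=[("M", rl)] + ([("S", clip_right)] if clip_right else []),
            mapq=mapq, seq=r2_ref + clip_right_seq, qual=None,
            is_supplementary=False, is_read2=False, is_merged=False, umi_raw=umi)
        r2 = AlignedSegment(
            qname=qname, sample=sample, chrom=chrom, pos=start, strand="+",
            cigar=([("S", clip_left)] if clip_left else []) + [("M", rl)],
            mapq=mapq, seq=clip_left_seq + r1_ref, qual=None,
            is_supplementary=False, is_read2=True, is_merged=False, umi_raw=umi)
    return [r1, r2]


def brute_force_grouping(items, same_group):
    """Transitive-closure partition of items under a symmetric pairwise
    predicate, by exhaustive union-find."""
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(items)), 2):
        if same_group(items[i], items[j]):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    groups = {}
    for i in range(len(items)):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


# ---------------------------------------------------------------------------
# Independent microhomology placement-enumeration oracle
# ---------------------------------------------------------------------------

def _oriented_flank(genome, node: JunctionNode, n: int, into: bool) -> str:
    """Reference flank sequence in molecule orientation, rebuilt from
    scratch (independent of the implementation's flank helpers)."""
    length = genome.chrom_length(node.chrom)
    if into:       # n bases ending at the node, reading toward the junction
        if node.side == "L":
            lo = max(1, node.pos - n + 1)
            return genome.fetch(node.chrom, lo, node.pos)
        hi = min(length, node.pos + n - 1)
        return revcomp(genome.fetch(node.chrom, node.pos, hi))
    if node.side == "R":   # n bases from the node, reading away
        hi = min(length, node.pos + n - 1)
        return genome.fetch(node.chrom, node.pos, hi)
    lo = max(1, node.pos - n + 1)
    return revcomp(genome.fetch(node.chrom, lo, node.pos))


def _shift_node(node: JunctionNode, t: int, upstream: bool) -> JunctionNode:
    if upstream:
        sign = 1 if node.side == "L" else -1
    else:
        sign = 1 if node.side == "R" else -1
    return JunctionNode(node.chrom, node.pos + t * sign, node.side)


def placement_oracle(genome, node1: JunctionNode, node2: JunctionNode,
                     flank: int = 40, max_shift: int = 30) -> int:
    """Number of breakpoint placements producing the identical junction
    molecule sequence, minus one (= the microhomology metric for
    non-insert junctions), by exhaustive shift enumeration."""
    ref_seq = (_oriented_flank(genome, node1, flank, into=True)
               + _oriented_flank(genome, node2, flank, into=False))
    count = 0
    mid_r = len(ref_seq) // 2
    for t in range(-max_shift, max_shift + 1):
        n1 = _shift_node(node1, t, upstream=True)
        n2 = _shift_node(node2, t, upstream=False)
        left = _oriented_flank(genome, n1, flank + max_shift, into=True)
        right = _oriented_flank(genome, n2, flank + max_shift, into=False)
        s = left + right
        mid_s = len(left)          # the shifted placement's junction index
        # a placement shifted by t puts its junction t molecule bases
        # downstream of the original one; realign before comparing
        w = min(mid_r, len(ref_seq) - mid_r, mid_s - abs(t), len(s) - mid_s - abs(t))
        if w <= 0:
            continue
        if ref_seq[mid_r - w:mid_r + w] == s[mid_s - w - t:mid_s + w - t]:
            count += 1
    return count - 1


# ---------------------------------------------------------------------------
# Simulator truth matching
# ---------------------------------------------------------------------------

def truth_key(row):
    return (row.chrom1, int(row.pos1), row.side1,
            row.chrom2, int(row.pos2), row.side2)


def call_key(sv):
    return (sv.node1.chrom, sv.node1.pos, sv.node1.side,
            sv.node2.chrom, sv.node2.pos, sv.node2.side)


def classify_calls(svs, truth_df, loose: int = 600):
    """Map each SV call to its simulated truth class: exact node match
    first, then a loose positional match for imprecise calls."""
    exact = {}
    for _, r in truth_df.iterrows():
        exact[truth_key(r)] = r
    out = []
    for sv in svs:
        r = exact.get(call_key(sv))
        if r is not None:
            out.append((sv, r.kind, True, r))
            continue
        hit = None
        for _, r in truth_df.iterrows():
            if (r.chrom1 == sv.node1.chrom and r.chrom2 == sv.node2.chrom
                    and abs(int(r.pos1) - sv.node1.pos) < loose
                    and abs(int(r.pos2) - sv.node2.pos) < loose):
                hit = r
                break
        out.append((sv, hit.kind if hit is not None else "unmatched", False, hit))
    return out
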