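"""Source-molecule reconstruction: UMI demultiplexing, grouping of read
pairs into source DNA molecules, strand family accounting and two-step
(single-strand then duplex) consensus building.

A "source molecule" is one input DNA fragment.  Read pairs that share the
same UMI indices (when applicable) and the same outer endpoints and outer
clip lengths within a 1 bp allowance are grouped into one molecule.  In
ligation (Y-adapter) libraries the two strands of one fragment yield read
pairs of opposite orientation and are grouped together, enabling duplex
consensus; in tagmentation libraries opposite orientations arise from
independent Tn5 cleavage events and remain separate molecules.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .seqio import AlignedSegment, revcomp

N_CODE = ord("N")
GAP_CODE = ord("-")
_BASE_CODES = np.array([ord(c) for c in "ACGT-"], dtype=np.uint8)


# ---------------------------------------------------------------------------
# UMI matching
# ---------------------------------------------------------------------------

class UmiWhitelist:
    """Expected UMI set (order defines the 1-based index).

    An observed UMI is assigned an index only when it lies within one
    mismatch of exactly one expected UMI; ambiguous or distant observations
    are rejected.
    """

    def __init__(self, umis: list[str]):
        if len(set(umis)) != len(umis):
            raise ValueError("expected UMIs must be unique")
        self.umis = [u.upper() for u in umis]
        self.length = len(self.umis[0])
        if any(len(u) != self.length for u in self.umis):
            raise ValueError("expected UMIs must share one length")
        self._exact = {u: i + 1 for i, u in enumerate(self.umis)}
        self._near: dict[str, int] = {}
        for i, u in enumerate(self.umis):
            for pos in range(self.length):
                for b in "ACGT":
                    if b == u[pos]:
                        continue
                    neighbor = u[:pos] + b + u[pos + 1:]
                    if neighbor in self._exact:
                        continue  # exact match wins; handled by _exact
                    if neighbor in self._near and self._near[neighbor] != i + 1:
                        self._near[neighbor] = 0  # ambiguous
                    else:
                        self._near[neighbor] = i + 1

    @classmethod
    def from_file(cls, path: str) -> "UmiWhitelist":
        with open(path) as fh:
            umis = [line.strip().upper() for line in fh if line.strip()]
        return cls(umis)

    def match(self, observed: str) -> Optional[int]:
        """Index (1-based) of the unique expected UMI within Hamming
        distance 1, or None (reject)."""
        if len(observed) != self.length:
            return None
        observed = observed.upper()
        idx = self._exact.get(observed)
        if idx is not None:
            return idx
        idx = self._near.get(observed, 0)
        return idx or None


def match_umi(observed: str, expected: list[str] | UmiWhitelist) -> Optional[int]:
    wl = expected if isinstance(expected, UmiWhitelist) else UmiWhitelist(list(expected))
    return wl.match(observed)


# ---------------------------------------------------------------------------
# Consensus primitives
# ---------------------------------------------------------------------------

def consensus_matrix(rows: np.ndarray, threshold: float = 2 / 3) -> np.ndarray:
    """Column-wise consensus of a (n_reads, n_cols) uint8 base matrix.

    0 marks a position not covered by a read and does not vote; 'N' input
    bases do not vote either.  A column is called when the modal base
    reaches `threshold` of the covering reads, else masked 'N'.
    """
    n, m = rows.shape
    if n == 1:
        out = rows[0].copy()
        out[out == 0] = N_CODE
        return out
    counts = np.zeros((len(_BASE_CODES), m), dtype=np.int32)
    for k, code in enumerate(_BASE_CODES):
        counts[k] = (rows == code).sum(axis=0)
    cover = counts.sum(axis=0)
    best = counts.argmax(axis=0)
    bestn = counts.max(axis=0)
    out = np.full(m, N_CODE, dtype=np.uint8)
    ok = cover > 0
    frac_ok = np.zeros(m, dtype=bool)
    # the 0.667 threshold is a rounding of 2/3: exactly two thirds passes
    frac_ok[ok] = bestn[ok] + 1e-9 >= threshold * cover[ok]
    out[frac_ok] = _BASE_CODES[best[frac_ok]]
    return out


def call_consensus(seqs: list[str], threshold: float = 2 / 3,
                   max_depth: int = 11, rng: np.random.Generator | None = None) -> str:
    """Consensus of equal-length sequences of one strand family, with
    seeded downsampling to `max_depth` and N-masking below `threshold`."""
    if not seqs:
        raise ValueError("empty family")
    if len(seqs) > max_depth:
        rng = rng or np.random.default_rng(0)
        pick = rng.choice(len(seqs), size=max_depth, replace=False)
        seqs = [seqs[i] for i in sorted(pick)]
    rows = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    rows = rows.copy()
    rows[rows == N_CODE] = 0
    return consensus_matrix(rows, threshold).tobytes().decode()


def duplex_consensus(strand1: str, strand2: str) -> str:
    """Agreement of two strand consensuses: disagreement or either-N -> N."""
    a = np.frombuffer(strand1.encode(), dtype=np.uint8)
    b = np.frombuffer(strand2.encode(), dtype=np.uint8)
    out = a.copy()
    out[(a != b) | (a == N_CODE) | (b == N_CODE)] = N_CODE
    return out.tobytes().decode()


# ---------------------------------------------------------------------------
# Molecule path model
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class PathSeg:
    """One aligned segment in molecule (fragment top-strand) order."""
    chrom: str
    start: int            # reference span, 1-based inclusive
    end: int
    frag_strand: str      # orientation relative to the molecule top strand
    mapq: int
    record: AlignedSegment


@dataclass(slots=True)
class Marker:
    """Relation between consecutive path segments: a sequenced split
    junction, or the unsequenced boundary between the two mates."""
    kind: str             # 'split' | 'pair'
    insert_len: int = 0
    insert_seq: str = ""


@dataclass(slots=True)
class MoleculePath:
    segs: list[PathSeg]
    markers: list[Marker]

    def entry_node(self) -> tuple[str, int, str]:
        s = self.segs[0]
        return (s.chrom, s.start, "R") if s.frag_strand == "+" else (s.chrom, s.end, "L")

    def exit_node(self) -> tuple[str, int, str]:
        s = self.segs[-1]
        return (s.chrom, s.end, "L") if s.frag_strand == "+" else (s.chrom, s.start, "R")


def _read_orient_qspan(rec: AlignedSegment) -> tuple[int, int]:
    """Aligned query interval in the sequenced-read orientation."""
    qs, qe = rec.query_span()
    if rec.strand == "+":
        return qs, qe
    total = sum(n for op, n in rec.cigar if op in "MIS=X")
    return total - qe, total - qs


def _read_path(records: list[AlignedSegment], flip: bool) -> list[PathSeg]:
    """Order one read's segments along the fragment top strand.  `flip` is
    True for mate-2 records (sequenced from the opposite fragment end)."""
    recs = sorted(records, key=lambda r: _read_orient_qspan(r)[0])
    if flip:
        recs = recs[::-1]
    out = []
    for r in recs:
        strand = r.strand if not flip else ("-" if r.strand == "+" else "+")
        out.append(PathSeg(chrom=r.chrom, start=r.pos, end=r.ref_end,
                           frag_strand=strand, mapq=r.mapq, record=r))
    return out


def _segments_compatible(a: PathSeg, b: PathSeg, slop: int = 5) -> bool:
    """True when two segments (one from each mate) cover the same part of
    the fragment: same chrom/orientation with overlapping or near-abutting
    reference spans."""
    return (a.chrom == b.chrom and a.frag_strand == b.frag_strand
            and b.start <= a.end + slop and a.start <= b.end + slop)


def _split_marker(prev: PathSeg, nxt: PathSeg, read_records: list[AlignedSegment]) -> Marker:
    """Marker for a within-read split junction, extracting any unaligned
    (de novo inserted) query bases between the two alignments."""
    p0, p1 = _read_orient_qspan(prev.record), _read_orient_qspan(nxt.record)
    lo, hi = sorted([p0, p1])
    gap = hi[0] - lo[1]
    ins = ""
    if gap > 0:
        # any record of this read carries the full query sequence
        rec = max(read_records, key=lambda r: len(r.seq))
        seq_ro = rec.seq if rec.strand == "+" else revcomp(rec.seq)
        ins = seq_ro[lo[1]:hi[0]]
        if prev.record.is_read2 and not prev.record.is_merged:
            ins = revcomp(ins)
    return Marker("split", max(gap, 0), ins)


def build_molecule_path(segments: list[AlignedSegment]) -> Optional[MoleculePath]:
    """Reconstruct the molecule's segment path from all alignments of one
    template (primary + supplementary, both mates).

    Returns None when no usable segments remain.
    """
    read1 = [s for s in segments if not s.is_read2]
    read2 = [s for s in segments if s.is_read2]
    if not read1 and not read2:
        return None
    path1 = _read_path(read1, flip=False) if read1 else []
    path2 = _read_path(read2, flip=True) if read2 else []
    if not path1:
        # orient by mate 2 alone: flip so its own 5' end is the entry
        path1, path2, read1, read2 = path2, [], read2, []

    # reconcile: the largest k such that the last k segments of path1 cover
    # the same fragment parts as the first k of path2
    k_best = 0
    for k in range(min(len(path1), len(path2)), 0, -1):
        if all(_segments_compatible(path1[len(path1) - k + i], path2[i])
               for i in range(k)):
            k_best = k
            break
    segs: list[PathSeg] = []
    markers: list[Marker] = []
    merged_zone_start = len(path1) - k_best
    for i, seg in enumerate(path1):
        if i > 0:
            markers.append(_split_marker(path1[i - 1], seg, read1))
        if i >= merged_zone_start and k_best:
            other = path2[i - merged_zone_start]
            seg = PathSeg(chrom=seg.chrom,
                          start=min(seg.start, other.start),
                          end=max(seg.end, other.end),
                          frag_strand=seg.frag_strand,
                          mapq=max(seg.mapq, other.mapq),
                          record=seg.record)
        segs.append(seg)
    tail = path2[k_best:]
    for j, seg in enumerate(tail):
        if j == 0 and k_best == 0:
            markers.append(Marker("pair"))
        elif j == 0:
            markers.append(_split_marker(path2[k_best - 1], seg, read2))
        else:
            markers.append(_split_marker(tail[j - 1], seg, read2))
        segs.append(seg)
    return MoleculePath(segs, markers)


def _ref_aligned_arrays(rec: AlignedSegment) -> list[tuple[str, int, np.ndarray]]:
    """Expand a record into per-reference-position base arrays.  Deletions
    contribute '-' symbols; insertions are skipped (junction inserts are
    handled at the path level)."""
    out = []
    seq = np.frombuffer(rec.seq.encode(), dtype=np.uint8)
    qpos, rpos = 0, rec.pos
    cur_start, parts = None, []
    for op, n in rec.cigar:
        if op in "M=X":
            if cur_start is None:
                cur_start = rpos
            parts.append(seq[qpos:qpos + n])
            qpos += n
            rpos += n
        elif op == "D":
            if cur_start is None:
                cur_start = rpos
            parts.append(np.full(n, GAP_CODE, dtype=np.uint8))
            rpos += n
        elif op == "I":
            qpos += n
        elif op in "SH":
            qpos += n if op == "S" else 0
        elif op == "N":
            if parts:
                out.append((rec.chrom, cur_start, np.concatenate(parts)))
            cur_start, parts = None, []
            rpos += n
    if parts:
        out.append((rec.chrom, cur_start, np.concatenate(parts)))
    return out


def _outer_clip_seqs(path: MoleculePath) -> tuple[str, str]:
    """Soft-clipped query bases beyond the molecule's two outer ends, in
    molecule orientation (entry clip ends just before the entry base; exit
    clip starts just after the exit base)."""
    first, last = path.segs[0], path.segs[-1]

    def clip(seg: PathSeg, side: str) -> str:
        rec = seg.record
        if (seg.frag_strand == "+") == (side == "entry"):
            raw = rec.seq[:rec.clip_left] if rec.clip_left else ""
            return raw if seg.frag_strand == "+" else revcomp(raw)
        raw = rec.seq[len(rec.seq) - rec.clip_right:] if rec.clip_right else ""
        return raw if seg.frag_strand == "+" else revcomp(raw)

    return clip(first, "entry"), clip(last, "exit")


# ---------------------------------------------------------------------------
# Molecule key and collation
# ---------------------------------------------------------------------------

@dataclass(slots=True, frozen=True)
class MoleculeKey:
    """Canonical grouping key: ordered outer endpoints with their outer
    clip lengths, canonicalized UMI indices and, in tagmentation mode, the
    strand orientation."""
    end1: tuple[str, int, str]
    end2: tuple[str, int, str]
    clip1: int
    clip2: int
    umi: Optional[tuple[int, int]]
    strand_index: Optional[int]   # None in ligation mode (strands share a key)

    def signature(self) -> str:
        u = f"{self.umi[0]}-{self.umi[1]}" if self.umi else "."
        s = "." if self.strand_index is None else str(self.strand_index)
        return (f"{self.end1[0]}:{self.end1[1]}:{self.end1[2]}:{self.clip1}/"
                f"{self.end2[0]}:{self.end2[1]}:{self.end2[2]}:{self.clip2}/{u}/{s}")


@dataclass(slots=True)
class SourceMolecule:
    id: str
    sample: str
    key: MoleculeKey
    strand_family: list[int]
    is_duplex: bool
    path: MoleculePath
    consensus: dict[str, list[tuple[str, int, np.ndarray]]]
    entry_clip_seq: str
    exit_clip_seq: str
    mol_class: str = "proper"
    shared_outer: bool = False

    @property
    def n_read_pairs(self) -> int:
        return self.strand_family[0] + self.strand_family[1]

    def outer_nodes(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return self.path.entry_node(), self.path.exit_node()

    def effective_consensus(self) -> list[tuple[str, int, np.ndarray]]:
        return self.consensus["duplex"] if "duplex" in self.consensus \
            else self.consensus.get("strand0") or self.consensus["strand1"]


@dataclass(slots=True)
class _ReadPairEvidence:
    strand_index: int
    arrays: list[tuple[str, int, np.ndarray]]
    score: float
    path: Optional[MoleculePath]
    entry_clip: str
    exit_clip: str


class _Anchor:
    __slots__ = ("key", "members", "best")

    def __init__(self, key: MoleculeKey):
        self.key = key
        self.members: list[_ReadPairEvidence] = []
        self.best: Optional[_ReadPairEvidence] = None

    def add(self, ev: _ReadPairEvidence) -> None:
        if self.best is None or ev.score > self.best.score:
            if self.best is not None:
                self.best.path = None
            self.best = ev
        else:
            ev.path = None
        self.members.append(ev)


@dataclass
class CollateStats:
    n_groups: int = 0
    n_retained: int = 0
    dropped_mapq: int = 0
    dropped_umi: int = 0
    umi_length_mismatch: int = 0


def _node_sort_key(node: tuple[str, int, str], chrom_order: dict[str, int]):
    return (chrom_order.get(node[0], 1 << 30), node[1], node[2])


def collate_molecules(groups: Iterable[list[AlignedSegment]],
                      mode: str = "ligation",
                      mapq_min: int = 20,
                      allowance: int = 1,
                      umi_whitelist: UmiWhitelist | None = None,
                      consensus_threshold: float = 2 / 3,
                      consensus_max_depth: int = 11,
                      seed: int = 0,
                      sample: str = "S1",
                      chrom_order: dict[str, int] | None = None,
                      ) -> tuple[list[SourceMolecule], CollateStats]:
    """Group name-grouped alignment templates into source molecules and
    build per-strand and duplex consensus sequences.

    Endpoint keys are compared with the first-seen read pair of each group
    acting as the anchor; every coordinate (both endpoints and both outer
    clip lengths) may differ by at most `allowance` bases.
    """
    if mode not in ("ligation", "tagmentation"):
        raise ValueError(f"unknown library mode {mode!r}")
    chrom_order = chrom_order or {}
    stats = CollateStats()
    buckets: dict[tuple, dict[int, list[_Anchor]]] = {}
    anchors: list[_Anchor] = []

    for group in groups:
        stats.n_groups += 1
        usable = [s for s in group if s.mapq > mapq_min]
        if not usable:
            stats.dropped_mapq += 1
            continue
        path = build_molecule_path(usable)
        if path is None:
            stats.dropped_mapq += 1
            continue
        entry, exit_ = path.entry_node(), path.exit_node()
        clip_entry = _path_clip(path, "entry")
        clip_exit = _path_clip(path, "exit")
        # canonical endpoint order
        if _node_sort_key(entry, chrom_order) <= _node_sort_key(exit_, chrom_order):
            e1, e2, c1, c2, strand_index = entry, exit_, clip_entry, clip_exit, 0
        else:
            e1, e2, c1, c2, strand_index = exit_, entry, clip_exit, clip_entry, 1

        umi_idx = None
        if umi_whitelist is not None:
            raw = next((s.umi_raw for s in usable if s.umi_raw), None)
            if raw is None:
                stats.dropped_umi += 1
                continue
            i1 = umi_whitelist.match(raw[0])
            i2 = umi_whitelist.match(raw[1])
            if len(raw[0]) != umi_whitelist.length or len(raw[1]) != umi_whitelist.length:
                stats.umi_length_mismatch += 1
            if i1 is None or i2 is None:
                stats.dropped_umi += 1
                continue
            umi_idx = (i1, i2) if strand_index == 0 else (i2, i1)

        key = MoleculeKey(end1=e1, end2=e2, clip1=c1, clip2=c2, umi=umi_idx,
                          strand_index=strand_index if mode == "tagmentation" else None)
        ev = _ReadPairEvidence(
            strand_index=strand_index,
            arrays=[arr for seg in path.segs
                    for arr in _ref_aligned_arrays(seg.record)],
            score=_pair_score(path),
            path=path,
            entry_clip="", exit_clip="")
        ev.entry_clip, ev.exit_clip = _outer_clip_seqs(path)

        bucket_key = (e1[0], e1[2], e2[0], e2[2], umi_idx, key.strand_index)
        sub = buckets.setdefault(bucket_key, {})
        hit = None
        for p in (e1[1] - allowance, e1[1], e1[1] + allowance) if allowance else (e1[1],):
            for anchor in sub.get(p, ()):  # anchors bucketed by their own end1 pos
                k = anchor.key
                if (abs(k.end2[1] - e2[1]) <= allowance
                        and abs(k.clip1 - c1) <= allowance
                        and abs(k.clip2 - c2) <= allowance
                        and abs(k.end1[1] - e1[1]) <= allowance):
                    hit = anchor
                    break
            if hit:
                break
        if hit is None:
            hit = _Anchor(key)
            sub.setdefault(e1[1], []).append(hit)
            anchors.append(hit)
        hit.add(ev)
        stats.n_retained += 1

    molecules = []
    for i, anchor in enumerate(anchors):
        molecules.append(_finalize_molecule(
            anchor, f"{sample}.m{i + 1}", sample, mode,
            consensus_threshold, consensus_max_depth, seed))
    return molecules, stats


def _path_clip(path: MoleculePath, side: str) -> int:
    seg = path.segs[0] if side == "entry" else path.segs[-1]
    rec = seg.record
    if (seg.frag_strand == "+") == (side == "entry"):
        return rec.clip_left
    return rec.clip_right


def _pair_score(path: MoleculePath) -> float:
    total = 0.0
    seen = set()
    for seg in path.segs:
        rid = id(seg.record)
        if rid in seen:
            continue
        seen.add(rid)
        if seg.record.qual:
            total += sum(ord(c) - 33 for c in seg.record.qual)
        else:
            total += len(seg.record.seq)
    return total


def _family_rng(seed: int, key: MoleculeKey) -> np.random.Generator:
    h = zlib.crc32(key.signature().encode()) & 0x7FFFFFFF
    return np.random.default_rng((seed & 0x7FFFFFFF, h))


def _strand_consensus_arrays(members: list[_ReadPairEvidence],
                             frame: list[tuple[str, int, int]],
                             threshold: float, max_depth: int,
                             rng: np.random.Generator,
                             ) -> list[tuple[str, int, np.ndarray]]:
    if len(members) > max_depth:
        pick = rng.choice(len(members), size=max_depth, replace=False)
        members = [members[i] for i in sorted(pick)]
    out = []
    for chrom, start, end in frame:
        width = end - start + 1
        rows = []
        for m in members:
            row = None
            for c, s, arr in m.arrays:
                if c != chrom or s > end or s + len(arr) - 1 < start:
                    continue
                if row is None:
                    row = np.zeros(width, dtype=np.uint8)
                lo = max(start, s)
                hi = min(end, s + len(arr) - 1)
                row[lo - start:hi - start + 1] = arr[lo - s:hi - s + 1]
            if row is not None:
                rows.append(row)
        if not rows:
            out.append((chrom, start, np.full(width, N_CODE, dtype=np.uint8)))
            continue
        mat = np.vstack(rows)
        mat[mat == N_CODE] = 0
        out.append((chrom, start, consensus_matrix(mat, threshold)))
    return out


def _finalize_molecule(anchor: _Anchor, mol_id: str, sample: str, mode: str,
                       threshold: float, max_depth: int, seed: int) -> SourceMolecule:
    key = anchor.key
    rep = anchor.best
    path = rep.path
    frame = [(s.chrom, s.start, s.end) for s in path.segs]
    fam = [0, 0]
    by_strand: dict[int, list[_ReadPairEvidence]] = {0: [], 1: []}
    for m in anchor.members:
        fam[m.strand_index] += 1
        by_strand[m.strand_index].append(m)
    rng = _family_rng(seed, key)
    consensus: dict[str, list[tuple[str, int, np.ndarray]]] = {}
    for sidx in (0, 1):
        if by_strand[sidx]:
            consensus[f"strand{sidx}"] = _strand_consensus_arrays(
                by_strand[sidx], frame, threshold, max_depth, rng)
    is_duplex = mode == "ligation" and fam[0] >= 1 and fam[1] >= 1
    if is_duplex:
        dup = []
        for (c, s, a), (_, _, b) in zip(consensus["strand0"], consensus["strand1"]):
            out = a.copy()
            out[(a != b) | (a == N_CODE) | (b == N_CODE)] = N_CODE
            dup.append((c, s, out))
        consensus["duplex"] = dup
    return SourceMolecule(
        id=mol_id, sample=sample, key=key,
        strand_family=fam, is_duplex=is_duplex,
        path=path, consensus=consensus,
        entry_clip_seq=rep.entry_clip, exit_clip_seq=rep.exit_clip)


# ---------------------------------------------------------------------------
# Mate overlap merging
# ---------------------------------------------------------------------------

def merge_overlapping_mates(seg1: AlignedSegment, seg2: AlignedSegment
                            ) -> Optional[AlignedSegment]:
    """Alignment-guided merge of a read pair with overlapping reference
    spans into one record.  In the overlap, agreeing bases are kept,
    disagreements resolve to the higher base quality, ties become N.

    Returns None (pair left unmerged) when the overlap is inconsistent:
    different chromosome, same orientation, non-simple CIGARs or
    non-overlapping spans.
    """
    for s in (seg1, seg2):
        if any(op not in "SM" for op, _ in s.cigar):
            return None
    if seg1.chrom != seg2.chrom or seg1.strand == seg2.strand:
        return None
    a, b = sorted((seg1, seg2), key=lambda s: s.pos)
    if b.pos > a.ref_end + 1:
        return None
    start, end = a.pos, max(a.ref_end, b.ref_end)
    width = end - start + 1
    seq = np.zeros((2, width), dtype=np.uint8)
    qual = np.zeros((2, width), dtype=np.int16)
    for i, s in enumerate((a, b)):
        qs, qe = s.query_span()
        sub = np.frombuffer(s.seq[qs:qe].encode(), dtype=np.uint8)
        off = s.pos - start
        seq[i, off:off + len(sub)] = sub
        q = (np.array([ord(c) - 33 for c in s.qual[qs:qe]], dtype=np.int16)
             if s.qual else np.full(len(sub), 30, dtype=np.int16))
        qual[i, off:off + len(sub)] = q
    out = np.where(seq[0] != 0, seq[0], seq[1]).astype(np.uint8)
    both = (seq[0] != 0) & (seq[1] != 0)
    disagree = both & (seq[0] != seq[1])
    take2 = disagree & (qual[1] > qual[0])
    tie = disagree & (qual[1] == qual[0])
    out[take2] = seq[1][take2]
    out[tie] = N_CODE
    return AlignedSegment(
        qname=seg1.qname, sample=seg1.sample, chrom=seg1.chrom, pos=start,
        strand="+", cigar=[("M", width)], mapq=max(seg1.mapq, seg2.mapq),
        seq=out.tobytes().decode(), qual=None,
        is_supplementary=False, is_read2=False, is_merged=True,
        umi_raw=seg1.umi_raw or seg2.umi_raw)
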