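"""Readers/writers for the standard formats the pipeline touches and the
genomic coordinate / capture-target model shared by all stages.

Internal coordinates are 1-based inclusive (SAM convention); BED I/O converts
at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class GenomeModel:
    """Reference genome: ordered chromosomes with a 1-based inclusive
    sequence accessor.

    Backed either by an in-memory dict of sequences (mutable, used by the
    simulator) or by an indexed FASTA via pyfaidx.
    """

    def __init__(self, sequences: dict[str, bytearray] | None = None,
                 fasta: "object | None" = None,
                 chrom_lengths: list[tuple[str, int]] | None = None):
        self._seqs = sequences
        self._fasta = fasta
        if sequences is not None:
            self.chromosomes = [(name, len(s)) for name, s in sequences.items()]
        elif chrom_lengths is not None:
            self.chromosomes = chrom_lengths
        else:
            raise ValueError("need sequences or chrom_lengths")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self._index = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        self._lengths = dict(self.chromosomes)

    # -- constructors -------------------------------------------------
    @classmethod
    def from_sequences(cls, seqs: dict[str, str | bytes | bytearray]) -> "GenomeModel":
        store = {}
        for name, s in seqs.items():
            if isinstance(s, str):
                s = s.encode()
            store[name] = bytearray(s.upper())
        return cls(sequences=store)

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeModel":
        import pyfaidx
        fa = pyfaidx.Fasta(str(path), sequence_always_upper=True)
        lengths = [(name, len(fa[name])) for name in fa.keys()]
        return cls(fasta=fa, chrom_lengths=lengths)

    # -- accessors ----------------------------------------------------
    def chrom_index(self, chrom: str) -> int:
        return self._index[chrom]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._index

    def chrom_length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive, uppercase."""
        if chrom not in self._index:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 1 or end > self._lengths[chrom] or start > end + 1:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside [1, {self._lengths[chrom]}]")
        if end < start:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start - 1:end].decode()
        return str(self._fasta[chrom][start - 1:end]).upper()

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    # -- mutation (in-memory backend only; used by the simulator) ------
    def set_slice(self, chrom: str, start: int, seq: str) -> None:
        if self._seqs is None:
            raise TypeError("genome is not mutable (FASTA-backed)")
        self._seqs[chrom][start - 1:start - 1 + len(seq)] = seq.upper().encode()

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, _ in self.chromosomes:
                seq = (self._seqs[name].decode() if self._seqs is not None
                       else str(self._fasta[name][:]))
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass(frozen=True)
class TargetRegion:
    """One capture target: the T span plus its two adjacent (A) flanks."""
    name: str
    chrom: str
    start: int           # 1-based inclusive capture span
    end: int
    adjacent_span: int = 250_000
    left_a: tuple[int, int] = (0, -1)    # clipped adjacent intervals
    right_a: tuple[int, int] = (0, -1)

    def t_length(self) -> int:
        return self.end - self.start + 1


class TargetRegionSet:
    """Capture targets with T/A/- point classification."""

    def __init__(self, regions: list[TargetRegion]):
        self.regions = regions
        self._trees: dict[str, IntervalTree] = {}
        for locus, r in enumerate(regions):
            tree = self._trees.setdefault(r.chrom, IntervalTree())
            tree.addi(r.start, r.end + 1, ("T", locus))
            for a0, a1 in (r.left_a, r.right_a):
                if a1 >= a0:
                    tree.addi(a0, a1 + 1, ("A", locus))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[TargetRegion]:
        return iter(self.regions)

    def classify_point(self, chrom: str, pos: int) -> tuple[str, Optional[int]]:
        """Classify a genomic base: T inside a capture span, A inside an
        adjacent flank, '-' otherwise.  T beats A when loci overlap; among
        equal codes the locus with the nearer capture span wins."""
        tree = self._trees.get(chrom)
        if tree is None:
            return "-", None
        hits = [iv.data for iv in tree.at(pos)]
        if not hits:
            return "-", None
        best = None
        for code, locus in hits:
            r = self.regions[locus]
            dist = max(r.start - pos, pos - r.end, 0)
            key = (0 if code == "T" else 1, dist)
            if best is None or key < best[0]:
                best = (key, code, locus)
        return best[1], best[2]

    def write_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")


class BedParseError(ValueError):
    pass


def load_targets(bed_path: str, adjacent_span: int = 250_000,
                 genome: GenomeModel | None = None) -> TargetRegionSet:
    """Load capture targets from a BED file (0-based half-open) and compute
    adjacent flanks, clipped to chromosome bounds when a genome is given."""
    regions: list[TargetRegion] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{bed_path}:{lineno}: expected >=3 columns")
            chrom = parts[0]
            try:
                b_start, b_end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise BedParseError(f"{bed_path}:{lineno}: non-integer coordinate") from e
            if b_end <= b_start:
                raise BedParseError(f"{bed_path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"target{len(regions) + 1}"
            start, end = b_start + 1, b_end  # to 1-based inclusive
            chrom_len = None
            if genome is not None and genome.has_chrom(chrom):
                chrom_len = genome.chrom_length(chrom)
            la0, la1 = start - adjacent_span, start - 1
            ra0, ra1 = end + 1, end + adjacent_span
            if la0 < 1:
                if la1 >= 1:
                    log.warning("left adjacent flank of %s clipped at chromosome start", name)
                la0 = 1
            if chrom_len is not None and ra1 > chrom_len:
                if ra0 <= chrom_len:
                    log.warning("right adjacent flank of %s clipped at chromosome end", name)
                ra1 = chrom_len
            regions.append(TargetRegion(
                name=name, chrom=chrom, start=start, end=end,
                adjacent_span=adjacent_span,
                left_a=(la0, la1) if la1 >= la0 else (0, -1),
                right_a=(ra0, ra1) if ra1 >= ra0 else (0, -1)))
    if not regions:
        raise BedParseError(f"{bed_path}: no target records")
    return TargetRegionSet(regions)


# ---------------------------------------------------------------------------
# Aligned segments and name-grouped parsing
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class AlignedSegment:
    """One alignment record, 1-based leftmost position, soft clips only at
    the ends of the CIGAR."""
    qname: str
    sample: str
    chrom: str
    pos: int
    strand: str                     # '+' or '-'
    cigar: list[tuple[str, int]]    # [('S', 5), ('M', 140), ...]
    mapq: int
    seq: str
    qual: Optional[str]
    is_supplementary: bool
    is_read2: bool
    is_merged: bool                 # unpaired record from pre-merged mates
    umi_raw: Optional[tuple[str, str]] = None

    @property
    def ref_end(self) -> int:
        """Rightmost aligned reference base (1-based inclusive)."""
        end = self.pos - 1
        for op, n in self.cigar:
            if op in "MD=X":
                end += n
        return end

    @property
    def clip_left(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] in "SH" else 0

    @property
    def clip_right(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] in "SH" else 0

    def query_span(self) -> tuple[int, int]:
        """Aligned query interval [qstart, qend) in the record's orientation."""
        qstart = self.clip_left
        qlen = sum(n for op, n in self.cigar if op in "MI=X")
        return qstart, qstart + qlen


_CIGAR_OPS = "MIDNSHP=X"


def _cigar_from_pysam(ct: list[tuple[int, int]]) -> list[tuple[str, int]]:
    return [(_CIGAR_OPS[op], n) for op, n in ct]


def cigar_str(cigar: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def _parse_umi_tag(rec) -> Optional[tuple[str, str]]:
    try:
        rx = rec.get_tag("RX")
    except KeyError:
        return None
    parts = rx.split("-")
    if len(parts) == 2:
        return parts[0], parts[1]
    return (rx, "")


class UngroupedInputError(ValueError):
    pass


def parse_alignment_groups(path_or_file, sample: str,
                           keep_unmapped: bool = False) -> Iterator[list[AlignedSegment]]:
    """Yield all segments (primary + supplementary, both mates) of one
    template together from a name-grouped SAM/BAM stream.

    Raises UngroupedInputError if a read name re-appears after another name
    (input must be name-sorted or name-collated).
    """
    if isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__"):
        af = pysam.AlignmentFile(str(path_or_file), check_sq=False)
    else:
        af = path_or_file
    seen: set[str] = set()
    current: Optional[str] = None
    group: list[AlignedSegment] = []
    for rec in af:
        if rec.is_unmapped and not keep_unmapped:
            continue
        if rec.query_name != current:
            if group:
                yield group
            if rec.query_name in seen:
                raise UngroupedInputError(
                    f"read name {rec.query_name!r} re-appears after another name; "
                    "input must be name-sorted (samtools sort -n)")
            if current is not None:
                seen.add(current)
            current = rec.query_name
            group = []
        group.append(AlignedSegment(
            qname=rec.query_name,
            sample=sample,
            chrom=rec.reference_name,
            pos=rec.reference_start + 1,
            strand="-" if rec.is_reverse else "+",
            cigar=_cigar_from_pysam(rec.cigartuples or []),
            mapq=rec.mapping_quality,
            seq=rec.query_sequence or "",
            qual=(pysam.qualities_to_qualitystring(rec.query_qualities)
                  if rec.query_qualities is not None else None),
            is_supplementary=rec.is_supplementary,
            is_read2=rec.is_read2,
            is_merged=not rec.is_paired,
            umi_raw=_parse_umi_tag(rec),
        ))
    if group:
        yield group


# ---------------------------------------------------------------------------
# Breakend VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type (BND)">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=EVENT,Number=1,Type=String,Description="SV event identifier">',
    '##INFO=<ID=SVCLASS,Number=1,Type=String,Description="Del/Dup/Inv/Trans">',
    '##INFO=<ID=JXNMETRIC,Number=1,Type=Integer,Description='
    '"Signed junction metric: microhomology > 0, 0 blunt, -insertion length">',
    '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="De novo inserted junction bases">',
    '##INFO=<ID=MOLECULES,Number=1,Type=Integer,Description="Supporting source molecules">',
    '##INFO=<ID=READPAIRS,Number=1,Type=Integer,Description="Supporting read pairs">',
    '##INFO=<ID=DUPLEX,Number=1,Type=Integer,Description="Supporting duplex molecules">',
    '##INFO=<ID=OUTERCLIPS,Number=1,Type=Integer,Description="Outer-clip supporting molecules">',
    '##INFO=<ID=TARGETCLASS,Number=1,Type=String,Description="Two-letter capture target class">',
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Supporting molecules / mean target coverage">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Gap-only junction, breakpoints approximate">',
]


def _bnd_alt(ref_base: str, own_side: str, mate_chrom: str, mate_pos: int,
             mate_side: str) -> str:
    bracket = "[" if mate_side == "R" else "]"
    mate = f"{bracket}{mate_chrom}:{mate_pos}{bracket}"
    # side L: molecule extends left of pos, junction attaches on the right
    return ref_base + mate if own_side == "L" else mate + ref_base


def write_bnd_vcf(sv_calls: list, genome: GenomeModel, out: str,
                  source: str = "capsv") -> None:
    """Write SV calls as paired VCF breakend (SVTYPE=BND) records with
    mutual MATEID."""
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    for name, length in genome.chromosomes:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(_VCF_HEADER_LINES)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for sv in sv_calls:
        n1, n2 = sv.node1, sv.node2
        ok = True
        for n in (n1, n2):
            if not genome.has_chrom(n.chrom) or not (1 <= n.pos <= genome.chrom_length(n.chrom)):
                log.warning("SV %s breakend %s outside contig bounds; record skipped", sv.id, n)
                ok = False
        if not ok:
            continue
        common = [
            "SVTYPE=BND",
            f"EVENT={sv.id}",
            f"SVCLASS={sv.sv_type}",
            f"MOLECULES={sv.n_molecules}",
            f"READPAIRS={sv.n_read_pairs}",
            f"DUPLEX={sv.n_duplex}",
            f"OUTERCLIPS={sv.n_outer_clips}",
            f"TARGETCLASS={sv.target_class}",
        ]
        if sv.vaf is not None:
            common.append(f"VAF={sv.vaf:.6g}")
        if sv.imprecise:
            common.append("IMPRECISE")
        if sv.junction_metric is not None:
            common.append(f"JXNMETRIC={sv.junction_metric}")
        if sv.insert_sequence:
            common.append(f"INSSEQ={sv.insert_sequence}")
        for i, (own, mate) in enumerate(((n1, n2), (n2, n1)), start=1):
            ref_base = genome.base(own.chrom, own.pos)
            alt = _bnd_alt(ref_base, own.side, mate.chrom, mate.pos, mate.side)
            info = ";".join([f"MATEID={sv.id}_{3 - i}"] + common)
            lines.append(f"{own.chrom}\t{own.pos}\t{sv.id}_{i}\t{ref_base}\t{alt}"
                         f"\t.\tPASS\t{info}")
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")
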