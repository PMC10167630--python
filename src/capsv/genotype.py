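"""Genotype-aware junction variant analysis: build the source individual's
unphased biallelic haplotype table from proper molecules, mark de novo
SNVs/indels in SV junction consensuses (bases absent from both the
reference and the haplotype allele lists) and test whether those variants
sit closer to the junction than expected by chance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .discovery import SVCall
from .molecule import SourceMolecule
from .seqio import GenomeModel, TargetRegionSet

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}
_ALLELE_SYMBOLS = "ACGT-"


@dataclass
class HaplotypeTable:
    """Biallelic genotypes at sufficiently covered positions.

    alleles maps (chrom, pos) -> frozenset of allele symbols (max 2);
    positions with more than two well-supported alleles are uncallable and
    excluded from both the table and the informative set.
    """
    alleles: dict[tuple[str, int], frozenset] = field(default_factory=dict)
    genotype_class: dict[tuple[str, int], str] = field(default_factory=dict)
    uncallable: set[tuple[str, int]] = field(default_factory=set)

    def is_covered(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self.alleles

    def lookup(self, chrom: str, pos: int) -> Optional[frozenset]:
        return self.alleles.get((chrom, pos))

    def __len__(self) -> int:
        return len(self.alleles)


def _region_list(targets: TargetRegionSet) -> list[tuple[str, int, int]]:
    out = []
    for r in targets:
        ivs = [(r.start, r.end)]
        for a0, a1 in (r.left_a, r.right_a):
            if a1 >= a0:
                ivs.append((a0, a1))
        out.extend((r.chrom, s, e) for s, e in ivs)
    return out


def build_haplotypes(proper_molecules: Iterable[SourceMolecule],
                     genome: GenomeModel, targets: TargetRegionSet,
                     min_depth: int = 10,
                     min_allele_fraction: float = 0.2) -> HaplotypeTable:
    """Pileup of unique proper-molecule consensus bases within and adjacent
    to each capture target; per position, alleles at fraction >=
    `min_allele_fraction` of covering molecules (at most two, by count)
    define the unphased genotype."""
    regions = _region_list(targets)
    counts: list[np.ndarray] = [
        np.zeros((len(_ALLELE_SYMBOLS), e - s + 1), dtype=np.int32)
        for _, s, e in regions]
    sym_index = {ord(c): i for i, c in enumerate(_ALLELE_SYMBOLS)}
    for mol in proper_molecules:
        for chrom, start, arr in mol.effective_consensus():
            for ri, (rc, rs, re) in enumerate(regions):
                if rc != chrom or start > re or start + len(arr) - 1 < rs:
                    continue
                lo = max(start, rs)
                hi = min(start + len(arr) - 1, re)
                sub = arr[lo - start:hi - start + 1]
                offs = np.arange(lo - rs, hi - rs + 1)
                for code, k in sym_index.items():
                    mask = sub == code
                    if mask.any():
                        np.add.at(counts[ri][k], offs[mask], 1)
    table = HaplotypeTable()
    for ri, (chrom, rs, re) in enumerate(regions):
        mat = counts[ri]
        depth = mat.sum(axis=0)
        ok = np.nonzero(depth >= min_depth)[0]
        for off in ok:
            col = mat[:, off]
            d = depth[off]
            strong = [(int(col[k]), _ALLELE_SYMBOLS[k])
                      for k in range(len(_ALLELE_SYMBOLS))
                      if col[k] >= min_allele_fraction * d]
            pos = rs + int(off)
            if len(strong) > 2:
                table.uncallable.add((chrom, pos))
                continue
            if not strong:
                continue
            strong.sort(reverse=True)
            alleles = frozenset(a for _, a in strong)
            ref = genome.base(chrom, pos)
            if alleles == {ref}:
                cls = "hom_ref"
            elif ref in alleles:
                cls = "het"
            elif len(alleles) == 1:
                cls = "hom_alt"
            else:
                cls = "het_alt"
            table.alleles[(chrom, pos)] = alleles
            table.genotype_class[(chrom, pos)] = cls
    return table


def haplotypes_from_vcf(path: str, genome: GenomeModel) -> HaplotypeTable:
    """Import known biallelic genotypes (SNVs only) from a VCF as the
    haplotype table, bypassing the internal pileup genotyper."""
    import pysam
    table = HaplotypeTable()
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if len(rec.ref) != 1 or any(len(a) != 1 for a in rec.alts or ()):
                continue
            sample_alleles: set[str] = set()
            if rec.samples:
                for s in rec.samples.values():
                    for a in (s.alleles or ()):
                        if a:
                            sample_alleles.add(a)
            else:
                sample_alleles = {rec.ref, *(rec.alts or ())}
            if not sample_alleles or len(sample_alleles) > 2:
                continue
            key = (rec.chrom, rec.pos)
            table.alleles[key] = frozenset(sample_alleles)
            ref = genome.base(rec.chrom, rec.pos)
            table.genotype_class[key] = ("hom_ref" if sample_alleles == {ref}
                                         else "het" if ref in sample_alleles
                                         else "hom_alt")
    return table


# ---------------------------------------------------------------------------
# De novo variant calling in junction consensuses
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class DeNovoVariant:
    sv_id: str
    chrom: str
    pos: int
    vtype: str          # 'SNV' | 'indel'
    observed: str
    distance: int       # bases from the junction, microhomology excluded (>= 1)
    flank: str          # 'left' | 'right'


@dataclass
class DeNovoResult:
    variants: list[DeNovoVariant]
    informative_by_sv: dict[str, int]
    coverage_by_distance: Counter      # (variant-containing SV, flank) crossings per distance


def call_denovo(svs: list[SVCall], haplotypes: HaplotypeTable,
                genome: GenomeModel) -> DeNovoResult:
    """Scan SV junction consensus flank columns for bases absent from both
    the reference genome and the haplotype allele lists.

    Distances are measured from the first non-microhomology base (distance
    1 = adjacent to the junction); N-masked columns and columns without a
    covered haplotype entry are not informative.  The weighted distance
    distribution counts, per distance, the variant-containing SV flanks
    whose informative span crosses it.
    """
    variants: list[DeNovoVariant] = []
    informative: dict[str, int] = {}
    per_sv_flank_distances: dict[tuple[str, str], set[int]] = {}
    for sv in svs:
        if sv.junction_metric is None or not sv.flank_columns:
            continue
        n_inf = 0
        for flank, j, chrom, pos, base in sv.flank_columns:
            mh = sv.mh_left if flank == "left" else sv.mh_right
            dist = j - mh
            if dist < 1 or base == "N":
                continue
            if not haplotypes.is_covered(chrom, pos):
                continue
            n_inf += 1
            per_sv_flank_distances.setdefault((sv.id, flank), set()).add(dist)
            ref = genome.base(chrom, pos)
            allowed = haplotypes.lookup(chrom, pos) | {ref}
            if base in allowed:
                continue
            vtype = "indel" if base == "-" else "SNV"
            variants.append(DeNovoVariant(sv_id=sv.id, chrom=chrom, pos=pos,
                                          vtype=vtype, observed=base,
                                          distance=dist, flank=flank))
        if n_inf == 0:
            continue  # no informative positions: SV excluded from stats
        informative[sv.id] = n_inf
    variant_svs = {v.sv_id for v in variants}
    coverage: Counter = Counter()
    for (sv_id, flank), dists in per_sv_flank_distances.items():
        if sv_id not in variant_svs:
            continue
        for d in dists:
            coverage[d] += 1
    return DeNovoResult(variants=variants, informative_by_sv=informative,
                        coverage_by_distance=coverage)


# ---------------------------------------------------------------------------
# Junction proximity permutation test
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class ProximityTestResult:
    p_value: float
    observed_median: float
    n_variants: int
    iterations: int
    seed: int


def junction_proximity_test(variants: list[DeNovoVariant] | list[int],
                            coverage_by_distance: dict[int, int] | Counter,
                            iterations: int = 10_000,
                            seed: int = 0,
                            finite_sample_correction: bool = False
                            ) -> ProximityTestResult:
    """Permutation test for junction proximity of de novo variants.

    Per iteration, n distances are drawn from the coverage-weighted
    distance distribution; the p-value is the fraction of iterations whose
    median is strictly less than the observed median (ties count as
    non-exceedances).  A small p indicates variants closer to the junction
    than expected given where variants could have been observed.
    """
    obs = np.array([v.distance if isinstance(v, DeNovoVariant) else int(v)
                    for v in variants], dtype=float)
    if obs.size == 0:
        raise ValueError("no observed variants")
    dists = np.array(sorted(coverage_by_distance), dtype=float)
    weights = np.array([coverage_by_distance[int(d)] for d in dists], dtype=float)
    if dists.size == 0 or weights.sum() <= 0:
        raise ValueError("empty coverage distribution")
    rng = np.random.default_rng(seed)
    sims = rng.choice(dists, size=(iterations, obs.size), p=weights / weights.sum())
    med = np.median(sims, axis=1)
    obs_med = float(np.median(obs))
    n_less = int((med < obs_med).sum())
    if finite_sample_correction:
        p = (n_less + 1) / (iterations + 1)
    else:
        p = n_less / iterations
    return ProximityTestResult(p_value=float(p), observed_median=obs_med,
                               n_variants=int(obs.size), iterations=iterations,
                               seed=seed)


def mann_whitney_proximity(variants: list[DeNovoVariant] | list[int],
                           coverage_by_distance: dict[int, int]) -> float:
    """Secondary rank test: observed distances vs the coverage-weighted
    population, one-sided toward proximity."""
    from scipy.stats import mannwhitneyu
    obs = [v.distance if isinstance(v, DeNovoVariant) else int(v) for v in variants]
    pop = np.repeat(np.array(sorted(coverage_by_distance)),
                    [coverage_by_distance[d] for d in sorted(coverage_by_distance)])
    return float(mannwhitneyu(obs, pop, alternative="less").pvalue)
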