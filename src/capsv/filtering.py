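"""Error-correction filters distinguishing true SV junctions from ligation
and chimeric-PCR artifacts, plus molecule-level coverage and VAF
computation.

Filter rationale (one predicate per artifact signature):

* ``require_duplex`` — chimeric PCR occurs after strand melting, so a
  chimeric junction can never be confirmed on both strands of a source
  molecule; demanding one duplex molecule eliminates that class.
* ``min_read_pairs`` — chimeric PCR arises late in amplification, so such
  molecules rarely show more than a single supporting read pair.
* ``exclude_shared_endpoints`` — chimeric templates recombine proper
  molecules that pre-exist in the library and therefore share outer
  endpoints with them.
* ``min_molecules`` — all wet-lab artifact mechanisms act after
  fragmentation, so multiple independent source molecules crossing the
  same junction establish a true SV; this also removes ligation artifacts,
  which duplex logic cannot (they form before strand melting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .discovery import SVCall
from .molecule import SourceMolecule
from .seqio import TargetRegionSet


@dataclass
class FilterSpec:
    """Adjustable SV filters.  Defaults reproduce the headline
    high-confidence setting: MAPQ 50 per flanking alignment, at least three
    read pairs, SVs detected in a single co-analyzed sample."""
    min_mapq: int = 50
    require_duplex: bool = False
    min_family_size: int = 0
    min_read_pairs: int = 3
    min_molecules: int = 1
    max_molecules: Optional[int] = None
    min_samples: int = 1
    max_samples: Optional[int] = 1
    exclude_shared_endpoints: bool = False
    min_sv_size: Optional[int] = None
    max_sv_size: Optional[int] = None
    allowed_target_classes: Optional[set[str]] = None

    def validate(self) -> None:
        for lo, hi, what in ((self.min_molecules, self.max_molecules, "molecules"),
                             (self.min_samples, self.max_samples, "samples"),
                             (self.min_sv_size, self.max_sv_size, "sv_size")):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"contradictory filter spec: min_{what} > max_{what}")


_FILTER_ORDER = ("mapq", "size", "target_class", "shared_endpoint",
                 "family", "read_pairs", "duplex", "molecules", "samples")


def _passes(sv: SVCall, spec: FilterSpec, which: str) -> bool:
    if which == "mapq":
        return sv.best_flank_mapq >= spec.min_mapq
    if which == "size":
        if sv.size is None:  # translocation: size filters not applicable
            return True
        if spec.min_sv_size is not None and sv.size < spec.min_sv_size:
            return False
        if spec.max_sv_size is not None and sv.size > spec.max_sv_size:
            return False
        return True
    if which == "target_class":
        return (spec.allowed_target_classes is None
                or sv.target_class in spec.allowed_target_classes)
    if which == "shared_endpoint":
        if not spec.exclude_shared_endpoints:
            return True
        # drop only when every supporting molecule shares an endpoint with
        # a proper molecule: a true SV can coexist with one recombinant
        return sv.shared_endpoint_count < sv.n_molecules
    if which == "family":
        return sv.max_family_size >= spec.min_family_size
    if which == "read_pairs":
        # read pairs (not source molecules) of the best-supported molecule
        return sv.max_molecule_read_pairs >= spec.min_read_pairs
    if which == "duplex":
        return not spec.require_duplex or sv.n_duplex >= 1
    if which == "molecules":
        n = sv.n_molecules
        if n < spec.min_molecules:
            return False
        return spec.max_molecules is None or n <= spec.max_molecules
    if which == "samples":
        n = sv.n_samples
        if n < spec.min_samples:
            return False
        return spec.max_samples is None or n <= spec.max_samples
    raise KeyError(which)


def apply_filters(svs: list[SVCall], spec: FilterSpec
                  ) -> tuple[list[SVCall], dict[str, int]]:
    """Apply every enabled predicate in fixed order, recording attrition
    (number of SVs removed) per predicate."""
    spec.validate()
    attrition = {name: 0 for name in _FILTER_ORDER}
    kept = []
    for sv in svs:
        for name in _FILTER_ORDER:
            if not _passes(sv, spec, name):
                attrition[name] += 1
                break
        else:
            kept.append(sv)
    return kept, attrition


def compute_coverage(proper_molecules: Iterable[SourceMolecule],
                     targets: TargetRegionSet) -> float:
    """Average capture-target coverage in unique source molecules per
    base: sum of molecule-span overlaps with capture spans divided by the
    total capture span length."""
    total_t = sum(r.t_length() for r in targets)
    if total_t == 0:
        raise ValueError("zero total target length")
    spans: dict[str, list[tuple[int, int]]] = {}
    for mol in proper_molecules:
        k = mol.key
        if k.end1[0] != k.end2[0]:
            continue
        spans.setdefault(k.end1[0], []).append((k.end1[1], k.end2[1]))
    covered = 0.0
    for r in targets:
        if r.chrom not in spans:
            continue
        arr = np.array(spans[r.chrom], dtype=np.int64)
        lo = np.minimum(arr[:, 0], arr[:, 1])
        hi = np.maximum(arr[:, 0], arr[:, 1])
        overlap = np.minimum(hi, r.end) - np.maximum(lo, r.start) + 1
        covered += overlap[overlap > 0].sum()
    return covered / total_t


def compute_vaf(sv: SVCall, coverage: float | dict[str, float]) -> dict[str, float]:
    """Per-sample VAF: total supporting molecules (split + gap + outer
    clip) divided by the average target-region coverage."""
    out: dict[str, float] = {}
    for sample in sorted(sv.samples):
        cov = coverage.get(sample) if isinstance(coverage, dict) else coverage
        if cov is None or cov <= 0:
            continue
        out[sample] = len({s.molecule.id for s in sv.supporters_in(sample)}) / cov
    sv.vaf_by_sample = out
    sv.vaf = max(out.values()) if out else None
    return out
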