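"""Stage orchestration: collate -> extract -> find -> filter -> genotype
-> stats, with YAML-configurable parameters, seeded determinism and
multi-sample co-analysis.  Stage outputs are plain TSV/VCF files with
documented schemas; the filter stage can re-run from a previously written
unfiltered SV table without repeating discovery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import discovery, filtering, genotype, junction, molecule, seqio
from .filtering import FilterSpec

log = logging.getLogger(__name__)

STAGES = ("collate", "extract", "find", "filter", "genotype", "stats")


@dataclass
class SampleSpec:
    name: str
    sam: str
    mode: str = "ligation"          # 'ligation' | 'tagmentation'
    umi_file: Optional[str] = None


@dataclass
class RunConfig:
    samples: list[SampleSpec]
    fasta: str
    bed: str
    outdir: str
    adjacent_span: int = 250_000
    mapq_min: int = 20
    allowance: int = 1
    consensus_threshold: float = 2 / 3   # the published 0.667, exactly two thirds
    consensus_max_depth: int = 11
    min_sv_size: int = 50
    max_proper_insert: Optional[int] = None    # None: estimated per run
    purge_allowance: int = 5
    min_clip: int = 5
    characterize_window: int = 150
    filter: FilterSpec = field(default_factory=FilterSpec)
    genotype_min_depth: int = 10
    genotype_min_allele_fraction: float = 0.2
    genotype_vcf: Optional[str] = None
    stats_iterations: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw.pop("samples")]
        fspec = FilterSpec(**raw.pop("filter", {}))
        if fspec.allowed_target_classes is not None:
            fspec.allowed_target_classes = set(fspec.allowed_target_classes)
        return cls(samples=samples, filter=fspec, **raw)

    def validate(self) -> None:
        for p in [self.fasta, self.bed] + [s.sam for s in self.samples]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        self.filter.validate()


class StageError(RuntimeError):
    pass


@dataclass
class PipelineState:
    genome: object = None
    targets: object = None
    molecules: dict = field(default_factory=dict)       # sample -> list
    candidates: list = field(default_factory=list)
    max_proper_insert: Optional[int] = None
    svs_unfiltered: list = field(default_factory=list)
    svs: list = field(default_factory=list)
    coverage: dict = field(default_factory=dict)
    haplotypes: object = None
    denovo: object = None
    proximity: object = None
    collate_stats: dict = field(default_factory=dict)


def estimate_max_proper_insert(spans: np.ndarray) -> int:
    """Robust upper bound on the proper molecule span: median plus four
    times the upper median-to-84th-percentile spread, insensitive to the
    minority of SV/artifact molecules in the span distribution."""
    if spans.size == 0:
        return 1000
    med = np.median(spans)
    p84 = np.quantile(spans, 0.84)
    return int(med + 4 * max(p84 - med, 1))


def _proper(state: PipelineState) -> list:
    return [m for mols in state.molecules.values() for m in mols
            if m.mol_class == "proper"]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_collate(cfg: RunConfig, state: PipelineState, out: Path) -> None:
    state.genome = seqio.GenomeModel.from_fasta(cfg.fasta)
    state.targets = seqio.load_targets(cfg.bed, adjacent_span=cfg.adjacent_span,
                                       genome=state.genome)
    chrom_order = {name: i for i, (name, _) in enumerate(state.genome.chromosomes)}
    for s in cfg.samples:
        wl = molecule.UmiWhitelist.from_file(s.umi_file) if s.umi_file else None
        groups = seqio.parse_alignment_groups(s.sam, sample=s.name)
        mols, stats = molecule.collate_molecules(
            groups, mode=s.mode, mapq_min=cfg.mapq_min, allowance=cfg.allowance,
            umi_whitelist=wl, consensus_threshold=cfg.consensus_threshold,
            consensus_max_depth=cfg.consensus_max_depth, seed=cfg.seed,
            sample=s.name, chrom_order=chrom_order)
        state.molecules[s.name] = mols
        state.collate_stats[s.name] = asdict(stats) if hasattr(stats, "__dict__") \
            or hasattr(stats, "__dataclass_fields__") else vars(stats)
        rows = [(m.id, m.key.signature(), m.strand_family[0], m.strand_family[1],
                 int(m.is_duplex)) for m in mols]
        pd.DataFrame(rows, columns=["id", "key", "family1", "family2", "duplex"]
                     ).to_csv(out / f"molecules_{s.name}.tsv", sep="\t", index=False)


def _stage_extract(cfg: RunConfig, state: PipelineState, out: Path) -> None:
    if not state.molecules:
        raise StageError("extract requires collate output; run collate first")
    chrom_order = {name: i for i, (name, _) in enumerate(state.genome.chromosomes)}
    # pass 1: provisional classification to estimate the proper insert bound
    spans = []
    for mols in state.molecules.values():
        for m in mols:
            k = m.key
            if k.end1[0] == k.end2[0]:
                spans.append(abs(k.end2[1] - k.end1[1]) + 1)
    mpi = cfg.max_proper_insert or estimate_max_proper_insert(np.array(spans))
    state.max_proper_insert = mpi
    cands = []
    for mols in state.molecules.values():
        for m in mols:
            cands.extend(junction.call_candidates(
                m, state.genome, min_sv_size=cfg.min_sv_size,
                max_proper_insert=mpi, chrom_order=chrom_order))
    proper_index = junction.build_proper_endpoint_index(_proper(state))
    junction.flag_shared_endpoints(cands, proper_index, allowance=cfg.allowance)
    state.candidates = cands
    rows = [(c.molecule.id, c.molecule.sample, str(c.node1), str(c.node2),
             c.sv_type, c.evidence, c.insert_len, c.min_flank_mapq,
             int(c.shared_outer_endpoint)) for c in cands]
    pd.DataFrame(rows, columns=["molecule", "sample", "node1", "node2", "type",
                                "evidence", "insert_len", "min_mapq", "shared"]
                 ).to_csv(out / "candidates.tsv", sep="\t", index=False)


def _stage_find(cfg: RunConfig, state: PipelineState, out: Path) -> None:
    if state.max_proper_insert is None:
        raise StageError("find requires extract output; run extract first")
    svs = discovery.discover(
        state.candidates, _proper(state), state.genome, state.targets,
        max_proper_insert=state.max_proper_insert,
        purge_allowance=cfg.purge_allowance, min_clip=cfg.min_clip,
        characterize_window=cfg.characterize_window)
    for s in cfg.samples:
        proper = [m for m in state.molecules[s.name] if m.mol_class == "proper"]
        state.coverage[s.name] = filtering.compute_coverage(proper, state.targets)
    for sv in svs:
        filtering.compute_vaf(sv, state.coverage)
    state.svs_unfiltered = svs
    _write_sv_table(svs, out / "svs_unfiltered.tsv")
    pd.DataFrame([(k, v) for k, v in state.coverage.items()],
                 columns=["sample", "coverage"]
                 ).to_csv(out / "coverage.tsv", sep="\t", index=False)


def _stage_filter(cfg: RunConfig, state: PipelineState, out: Path) -> None:
    if not state.svs_unfiltered:
        table = out / "svs_unfiltered.tsv"
        if table.exists():
            state.svs_unfiltered = read_sv_table(str(table))
        else:
            raise StageError("filter requires find output; run find first")
    kept, attrition = filtering.apply_filters(state.svs_unfiltered, cfg.filter)
    state.svs = kept
    _write_sv_table(kept, out / "svs.tsv")
    pd.DataFrame([(k, v) for k, v in attrition.items()],
                 columns=["predicate", "removed"]
                 ).to_csv(out / "attrition.tsv", sep="\t", index=False)
    if state.genome is not None:
        seqio.write_bnd_vcf(kept, state.genome, str(out / "svs.vcf"))


def _stage_genotype(cfg: RunConfig, state: PipelineState, out: Path) -> None:
    if not state.molecules:
        raise StageError("genotype requires collate output in the same run")
    if cfg.genotype_vcf:
        state.haplotypes = genotype.haplotypes_from_vcf(cfg.genotype_vcf, state.genome)
    else:
        state.haplotypes = genotype.build_haplotypes(
            _proper(state), state.genome, state.targets,
            min_depth=cfg.genotype_min_depth,
            min_allele_fraction=cfg.genotype_min_allele_fraction)
    svs = state.svs or state.svs_unfiltered
    state.denovo = genotype.call_denovo(svs, state.haplotypes, state.genome)
    rows = [(v.sv_id, v.chrom, v.pos, v.vtype, v.observed, v.distance, v.flank)
            for v in state.denovo.variants]
    pd.DataFrame(rows, columns=["sv", "chrom", "pos", "type", "observed",
                                "distance", "flank"]
                 ).to_csv(out / "denovo.tsv", sep="\t", index=False)


def _stage_stats(cfg: RunConfig, state: PipelineState, out: Path) -> None:
    if state.denovo is None:
        raise StageError("stats requires genotype output; run genotype first")
    rows = []
    if state.denovo.variants and state.denovo.coverage_by_distance:
        res = genotype.junction_proximity_test(
            state.denovo.variants, state.denovo.coverage_by_distance,
            iterations=cfg.stats_iterations, seed=cfg.seed)
        state.proximity = res
        rows.append(("n_variants", res.n_variants))
        rows.append(("observed_median_distance", res.observed_median))
        rows.append(("p_value", res.p_value))
        rows.append(("iterations", res.iterations))
        rows.append(("seed", res.seed))
    rows.append(("informative_svs", len(state.denovo.informative_by_sv)))
    rows.append(("informative_positions", sum(state.denovo.informative_by_sv.values())))
    pd.DataFrame(rows, columns=["metric", "value"]
                 ).to_csv(out / "stats.tsv", sep="\t", index=False)


_STAGE_FN = {"collate": _stage_collate, "extract": _stage_extract,
             "find": _stage_find, "filter": _stage_filter,
             "genotype": _stage_genotype, "stats": _stage_stats}


def run_pipeline(cfg: RunConfig, stages: Optional[list[str]] = None
                 ) -> PipelineState:
    """Run the requested stages in fixed order, writing versioned TSV/VCF
    outputs plus a machine-readable run log under cfg.outdir."""
    cfg.validate()
    stages = list(stages) if stages else list(STAGES)
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state = PipelineState()
    for stage in STAGES:
        if stage in stages:
            log.info("stage %s", stage)
            _STAGE_FN[stage](cfg, state, out)
    logrec = {
        "seed": cfg.seed,
        "stages": [s for s in STAGES if s in stages],
        "samples": [s.name for s in cfg.samples],
        "max_proper_insert": (int(state.max_proper_insert)
                              if state.max_proper_insert is not None else None),
        "coverage": {k: float(v) for k, v in state.coverage.items()},
        "collate": state.collate_stats,
        "n_candidates": len(state.candidates),
        "n_svs_unfiltered": len(state.svs_unfiltered),
        "n_svs": len(state.svs),
        "filter": {k: (sorted(v) if isinstance(v, set) else v)
                   for k, v in asdict(cfg.filter).items()},
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(logrec, sort_keys=True))
    return state


# ---------------------------------------------------------------------------
# SV table serialization (one row per SV; supporters as JSON)
# ---------------------------------------------------------------------------

def _write_sv_table(svs: list, path) -> None:
    rows = []
    for sv in svs:
        sups = [dict(id=s.molecule.id, sample=s.molecule.sample,
                     ev=s.evidence, f1=s.molecule.strand_family[0],
                     f2=s.molecule.strand_family[1],
                     dx=int(s.molecule.is_duplex),
                     sh=int(s.molecule.shared_outer),
                     mq=(s.candidate.min_flank_mapq if s.candidate else 60))
                for s in sv.supporters]
        rows.append(dict(
            id=sv.id, chrom1=sv.node1.chrom, pos1=sv.node1.pos, side1=sv.node1.side,
            chrom2=sv.node2.chrom, pos2=sv.node2.pos, side2=sv.node2.side,
            type=sv.sv_type, size=sv.size if sv.size is not None else -1,
            imprecise=int(sv.imprecise),
            metric=sv.junction_metric if sv.junction_metric is not None else "NA",
            insert=sv.insert_sequence, mh_left=sv.mh_left, mh_right=sv.mh_right,
            target_class=sv.target_class, n_molecules=sv.n_molecules,
            n_duplex=sv.n_duplex, n_read_pairs=sv.n_read_pairs,
            n_outer_clips=sv.n_outer_clips, max_family=sv.max_family_size,
            shared=sv.shared_endpoint_count, n_samples=sv.n_samples,
            reference_molecule=sv.reference_molecule or "",
            vaf=json.dumps(sv.vaf_by_sample), supporters=json.dumps(sups)))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class _StubCandidate:
    __slots__ = ("min_flank_mapq",)

    def __init__(self, mq: int):
        self.min_flank_mapq = mq


class _StubMolecule:
    """Lightweight supporter molecule reconstructed from an SV table row;
    carries exactly the attributes the filter and VAF stages consult."""
    __slots__ = ("id", "sample", "strand_family", "is_duplex", "shared_outer")

    def __init__(self, d: dict):
        self.id = d["id"]
        self.sample = d["sample"]
        self.strand_family = [d["f1"], d["f2"]]
        self.is_duplex = bool(d["dx"])
        self.shared_outer = bool(d["sh"])

    @property
    def n_read_pairs(self) -> int:
        return self.strand_family[0] + self.strand_family[1]


def read_sv_table(path: str) -> list:
    from .discovery import SVCall, Supporter
    from .junction import JunctionNode
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    svs = []
    for _, r in df.iterrows():
        sups = []
        for d in json.loads(r["supporters"]):
            sups.append(Supporter(_StubMolecule(d), d["ev"],
                                  _StubCandidate(d["mq"])))
        sv = SVCall(
            id=r["id"],
            node1=JunctionNode(r["chrom1"], int(r["pos1"]), r["side1"]),
            node2=JunctionNode(r["chrom2"], int(r["pos2"]), r["side2"]),
            sv_type=r["type"], imprecise=bool(r["imprecise"]), supporters=sups)
        sv.junction_metric = None if r["metric"] == "NA" else int(r["metric"])
        sv.insert_sequence = r["insert"] if isinstance(r["insert"], str) else ""
        sv.mh_left, sv.mh_right = int(r["mh_left"]), int(r["mh_right"])
        sv.target_class = r["target_class"]
        sv.reference_molecule = r["reference_molecule"] or None
        sv.vaf_by_sample = {k: float(v) for k, v in json.loads(r["vaf"]).items()}
        sv.vaf = max(sv.vaf_by_sample.values()) if sv.vaf_by_sample else None
        svs.append(sv)
    return svs
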