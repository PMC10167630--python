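import numpy as np
import pandas as pd
import pytest

from capsv.filtering import FilterSpec
from capsv.pipeline import RunConfig, SampleSpec, run_pipeline
from capsv.seqio import GenomeModel
from capsv.simulate import CloneSpec, SimConfig, simulate_run


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_genome():
    gen = np.random.default_rng(7)
    seqs = {f"chr{i + 1}": "".join("ACGT"[b] for b in gen.integers(0, 4, 5000))
            for i in range(2)}
    return GenomeModel.from_sequences(seqs)


def _run_pipeline_on(simdir, mode, adjacent_span, seed=1, stages=None,
                     fspec=None):
    samples = [SampleSpec(name="S1", sam=f"{simdir}/S1.sam", mode=mode,
                          umi_file=(f"{simdir}/umis.txt" if mode == "ligation"
                                    else None))]
    cfg = RunConfig(samples=samples, fasta=f"{simdir}/ref.fa",
                    bed=f"{simdir}/targets.bed", outdir=f"{simdir}/out",
                    adjacent_span=adjacent_span,
                    filter=fspec or FilterSpec(min_read_pairs=1), seed=seed)
    return run_pipeline(cfg, stages=stages or ["collate", "extract", "find"])


@pytest.fixture(scope="session")
def lig_run(tmp_path_factory):
    """Ligation-duplex library with a 40% SV clone plus chimeric-PCR and
    intermolecular-ligation artifacts; pipeline run through discovery."""
    d = tmp_path_factory.mktemp("lig_sim")
    cfg = SimConfig(seed=2025, n_chroms=3, chrom_length=60_000,
                    target_span=12_000, adjacent_span=5_000, depth=300,
                    clones=[CloneSpec(fraction=0.4, n_svs=9)],
                    chimeric_pcr_rate=0.006, ligation_chimera_rate=0.005)
    sim = simulate_run(cfg, str(d))
    state = _run_pipeline_on(str(d), "ligation", cfg.adjacent_span)
    truth_j = pd.read_csv(sim["samples"]["S1"]["truth_junctions"], sep="\t",
                          keep_default_na=False)
    truth_p = pd.read_csv(sim["samples"]["S1"]["truth_pairs"], sep="\t",
                          keep_default_na=False, dtype={"jid": str})
    return dict(cfg=cfg, dir=str(d), sim=sim, state=state,
                truth_junctions=truth_j, truth_pairs=truth_p)


@pytest.fixture(scope="session")
def tag_run(tmp_path_factory):
    """Tagmentation library with foldback-inversion artifacts and no
    ligation chimeras."""
    d = tmp_path_factory.mktemp("tag_sim")
    cfg = SimConfig(seed=404, n_chroms=3, chrom_length=60_000,
                    target_span=10_000, adjacent_span=5_000, depth=200,
                    mode="tagmentation",
                    clones=[CloneSpec(fraction=0.4, n_svs=3)],
                    foldback_rate=0.004, ligation_chimera_rate=0.0)
    sim = simulate_run(cfg, str(d))
    state = _run_pipeline_on(str(d), "tagmentation", cfg.adjacent_span)
    truth_j = pd.read_csv(sim["samples"]["S1"]["truth_junctions"], sep="\t",
                          keep_default_na=False)
    return dict(cfg=cfg, dir=str(d), sim=sim, state=state, truth_junctions=truth_j)
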