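# capsv

Error-minimized detection of rare structural-variant (SV) junctions in
targeted capture sequencing libraries.

Probe-capture sequencing with duplex (UMI-based) error correction is a
standard way to find single-nucleotide variants at very low allele
frequencies. Extending that sensitivity to SV *junctions* requires fighting
a different set of error mechanisms, each with a recognizable signature:

| error mechanism | when it arises | signature |
|---|---|---|
| intermolecular ligation | adapter ligation, before strand melting | blunt or 1-base A/T-insertion junctions; second endpoint anywhere in the genome; can be duplex-confirmed |
| chimeric PCR | template switching during amplification, after strand melting | large junction microhomology (peak 8–9 bp); single strand, single read pair; outer endpoints shared with proper library molecules |
| foldback synthesis | tagmentation library extension | small (< 1 kb) inversions with large microhomology |

`capsv` implements the full junction-calling stack for such libraries —
source-molecule reconstruction, strand-aware duplex consensus, split/gap
junction extraction, cross-molecule SV assembly, artifact-specific filters,
junction microhomology characterization, and junction-proximal de novo
variant statistics — together with a ground-truthed synthetic library
simulator that reproduces all three artifact classes, so every stage is
testable without external data.

It is aimed at people studying SV formation (common fragile sites,
genotoxicant exposure, somatic mosaicism) who need to count junctions that
may exist in only a single source DNA molecule.

## The model

**Source molecules.** Aligned, name-grouped read pairs are collapsed into
source DNA molecules: read pairs sharing the same UMI indices (matched to a
whitelist of 96 with at most one mismatch), the same two outer alignment
endpoints and the same outer soft-clip lengths, all within a 1 bp
allowance, derive from one input fragment. In ligation (Y-adapter)
libraries the two strands of a fragment produce mirror-orientation read
pairs and are grouped together; a molecule with at least one read pair from
each strand is *duplex*. In tagmentation libraries opposite orientations
are independent Tn5 products and stay separate.

**Consensus.** Per strand, up to 11 read pairs are downsampled and each
aligned column is called when the modal base reaches 2/3 of the covering
reads, else masked `N`; the duplex consensus keeps only bases on which both
strand consensuses agree.

**Junctions.** A molecule is a path of aligned segments described by nodes
`(chromosome, position, side)`, where side L/R is the direction the
molecule proceeds from that position. The two path extremes are the outer
nodes (the fragment ends); every junction between consecutive segments
contributes an inner node pair. Canonically sorted inner pairs map to SV
types: `(L, R) -> Del`, `(R, L) -> Dup`, equal sides `-> Inv`, different
chromosomes `-> Trans`. Junctions are evidenced either by split alignments
(primary + supplementary) or, when the junction falls in the unsequenced
gap between mates, by discordant pair geometry.

**SV assembly.** Candidates from all co-analyzed samples are sorted by
left node and broken into sets wherever consecutive left nodes are at
least one maximum-proper-insert apart; each set is re-sorted by right node
and split again. Within a call, likely duplicate molecules whose outer
endpoints differ by fewer than 5 bp in total are purged; proper molecules
clipped at the junction by at least 5 bases whose clipped sequence matches
the far flank are recovered as additional support; gap-only junctions are
reconstructed from the innermost aligned read ends and flagged imprecise.

**Junction metric.** For each precise call the signed junction metric is
the number of alternative breakpoint placements (microhomology) when
positive, 0 for blunt joints, and minus the length of any de novo inserted
sequence. Both breakends are classified against the capture design:
uppercase two-letter codes (`TT`, `TA`) mean both ends belong to the same
target locus (capture span T or adjacent region A); lowercase codes mark
the unexpected, usually artifactual, combinations.

**Filters and VAF.** Adjustable filters encode the artifact signatures:
require a duplex molecule (eliminates chimeric PCR), minimum read pairs in
the best-supported molecule (chimeras rarely exceed one), shared-endpoint
exclusion, and minimum independent molecules (removes every
post-fragmentation artifact class). The variant allele frequency of a call
is its total supporting molecules — split, gap and outer-clip — divided by
the mean capture-target coverage in unique molecules; a heterozygous SV
carried by a clone at fraction *f* has expected VAF *f*/2.

**De novo variants near junctions.** Proper molecules yield an unphased
biallelic genotype table; junction-consensus bases absent from both the
reference and the individual's alleles are presumptive de novo SNVs/indels.
Their distances from the junction (first non-microhomology base = distance
1) are tested against the coverage-weighted null by drawing the observed
number of variants over 10 000 iterations; the p-value is the fraction of
iterations whose median distance is below the observed median.

## Worked example

Simulate a small duplex capture library — two chromosomes with 10 kb
capture targets, a 10% clone heterozygous for four deletions, and chimeric
PCR artifacts — then run the pipeline:

```bash
cat > sim.yaml << 'YAML'
seed: 11
n_chroms: 2
chrom_length: 60000
target_span: 10000
adjacent_span: 5000
depth: 300
chimeric_pcr_rate: 0.005
clones:
  - fraction: 0.10
    n_svs: 4
YAML
capsv simulate -c sim.yaml -o sim

cat > run.yaml << 'YAML'
samples:
  - {name: S1, sam: sim/S1.sam, mode: ligation, umi_file: sim/umis.txt}
fasta: sim/ref.fa
bed: sim/targets.bed
outdir: out
adjacent_span: 5000
filter: {min_read_pairs: 3, min_mapq: 50}
YAML
capsv run -c run.yaml --seed 1
```

which prints

```
S1: {'proper': 26646, 'trueSV': 64, 'ligation': 0, 'chimericPCR': 117, 'foldback': 0, 'read_pairs': 54147}
SVs unfiltered: 118  filtered: 4
```

118 junctions are assembled before filtering — almost all of them the 117
injected chimeric-PCR artifacts — and the three-read-pair filter leaves
exactly the four planted deletions. `out/svs.tsv` shows them with exact
breakpoints and junction metrics (`metric 2` = 2 bp microhomology,
`metric -2` with `insert CG` = 2-base de novo insertion):

```
id     chrom1  pos1   side1  chrom2  pos2   side2  type  size  metric  insert  n_molecules  n_duplex  vaf
sv52   chr1    28808  L      chr1    28970  R      Del   162    2              19           3         0.064
sv83   chr1    33069  L      chr1    33274  R      Del   205   -2      CG      17           3         0.057
sv107  chr2    26847  L      chr2    27097  R      Del   250    0              13           6         0.044
sv115  chr2    29654  L      chr2    30013  R      Del   359    2              11           2         0.037
```

The VAFs scatter around the heterozygous expectation of 5% for a 10%
clone (mean target coverage here: 297 molecules per base). The same calls
are exported as VCF breakends (`SVTYPE=BND`) in `out/svs.vcf`.

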