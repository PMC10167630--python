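# Methods

This note records the models, conventions and numerical choices behind
`capsv`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Source-molecule reconstruction (collate)

Input is any name-grouped SAM/BAM stream of 2×151-style paired-end
alignments with soft clips, supplementary split alignments and optional
`RX` UMI tags. Alignment and quality trimming are upstream concerns; the
pipeline consumes aligned records (the simulator emits them directly).

*Endpoint keys.* Segments passing a mapping-quality floor (default:
MAPQ > 20) define the molecule's two outermost positions and outer
soft-clip lengths. Read pairs sharing UMI indices, endpoints and clip
lengths within a 1 bp allowance are one source molecule. The allowance is
applied per coordinate (each endpoint and each clip length may differ by
at most 1) against the first-seen read pair of a group, which acts as the
anchor; single-pass anchored grouping was chosen over transitive closure
for determinism. A property test bounds the difference: the two schemes
must agree whenever cluster spreads stay within the allowance of the
anchor and distinct keys are at least 3 bp apart, which is the regime real
families occupy.

*UMIs.* Observed UMIs are matched to the expected set of 96 allowing one
mismatch; the match must be unique, ambiguity rejects the read pair (the
expected sets generated by the simulator keep pairwise Hamming distance
at least 3, so ambiguity is structurally impossible there). Length
mismatches are counted separately. In ligation mode the UMI pair order is
swapped when canonicalizing bottom-strand read pairs.

*Library modes.* Ligation (Y-adapter) libraries group mirror-orientation
read pairs into one molecule and track read-pair counts per strand
(strand family sizes); a molecule with both families nonzero is duplex.
Tagmentation libraries cannot identify strands: opposite orientations at
the same endpoints are independent cleavage events and remain distinct
molecules.

*Consensus.* Two steps: per strand, then duplex. Families larger than 11
read pairs are downsampled with a per-molecule RNG derived from the run
seed and a CRC of the molecule key, so consensus is reproducible and
independent of input order. A column is called when the modal base
reaches the published fractional threshold of 0.667 — implemented as an
exact 2/3 with an epsilon, so that 2-of-3 passes and 7-of-11 fails — else
masked `N`. Bases are counted unweighted (base qualities do not weight the
vote). The duplex consensus keeps bases on which both strand consensuses
agree and masks disagreements. The representative read pair (highest
summed base quality, ties to the first seen) anchors the coordinate
frame; 1 bp endpoint jitter among family members is reconciled by
absolute reference position, not by string offset.

*Mate overlap merging* is available as a standalone operation (agreeing
bases kept, disagreements resolved to the higher base quality, ties to
`N`, inconsistent overlaps left unmerged). The collate stage does not need
it: overlapping mates contribute consistent votes to the same reference
columns, and the path builder reconciles mates that both cover a
junction.

## Junction extraction (extract)

Each molecule is a path of aligned segments in fragment order, described
by nodes `(chromosome, position, side)`; the side (L/R) is the direction
the molecule proceeds from that point. Within-read splits are junctions
with sequenced support; the mate boundary is a junction only when the pair
is discordant. Discordance is judged on the implied insert: for a simple
two-segment molecule that is the outer span, but when the molecule already
carries split evidence the span is inflated by the junction itself, so the
unsequenced gap between the flanking segments is judged locally instead.
The maximum proper insert size is estimated per run as
`median + 4·(p84 − median)` of the same-chromosome molecule span
distribution — a robust upper bound that a small fraction of SV and
artifact molecules cannot shift (the aligner-reported insert bound used
originally is metadata this pipeline does not have); it can be overridden
in the run configuration.

Same-chromosome junctions smaller than `min_sv_size` (default 50 bp) are
treated as indels, not SVs. Figure-style display cutoffs (e.g. 2 kb) are
reporting options, not calling thresholds. Candidates whose flanking
alignments fall below the configured MAPQ floor are retained but filtered
at the SV level. Molecules whose outer endpoints coincide (within the
1 bp allowance) with outer endpoints of properly paired molecules in the
same library are flagged: chimeric PCR recombines templates that pre-exist
in the library.

## SV assembly (find)

Candidates from all co-analyzed samples are clustered together by the
two-pass sort-and-split procedure (left nodes, then right nodes, breaking
wherever consecutive nodes are separated by at least the maximum proper
insert). Within a final set, split-evidence candidates with identical
inner nodes and insert length form one call — conflicting junctions in
one cluster therefore yield distinct calls — and gap candidates attach to
the nearest compatible precise junction (the junction must lie beyond each
inner read end, within one insert size; a 20 bp slop absorbs alignment
extension through junction microhomology). Leftover gap-only candidates
become an imprecise call whose nominal breakpoints are the innermost
aligned read ends; imprecise junctions carry no metric and are excluded
from junction-profile analyses.

*Duplicate purge.* Within one sample, supporters whose outer endpoints are
closer than 5 bp in total (strict inequality on the sum over both ends)
are considered optical/PCR re-observations; the lower-family-size molecule
is dropped. At high coverage this occasionally removes genuinely
independent molecules — the price of the rule, visible as a small downward
bias of VAFs.

*Junction metric.* The reference molecule is the split supporter whose
junction is most central in its sequenced span (ties: larger family, then
lexicographic id). For non-insert junctions the metric is the
microhomology — the number of alternative breakpoint placements minus one —
computed by base-wise extension of both flanks against the reference in
molecule orientation; an exhaustive placement-enumeration oracle in the
test suite verifies exact agreement on thousands of random junctions of
all four types. De novo inserts are the unaligned query bases between the
split alignments, reported as a negative metric with the sequence
attached.

Alignment placement conventions matter here. Split alignments are taken
at the upstream-maximal placement (the upstream flank absorbs the
homology tract), so called breakpoints are reproducible; an isolated
clipped molecule aligned only to the downstream flank ends at the
opposite placement extreme, `metric` bases back along both flanks.
Outer-clip recovery therefore probes both extremes: exit-type clips at
the called upstream node, entry-type clips at the shifted downstream
node, requiring at least 5 clipped bases and an exact match of
min(clip, 20) bases to the far flank (5 matching bases alone would be
permissive at the 4⁻⁵ level; 20 caps the comparison). With 1% sequencing
error a fraction of genuine junction clips fail the exact match; this is
accepted rather than loosened.

*Target classes.* Every breakend is classified T (capture span), A
(adjacent region, default 250 kb, configurable) or `-`; the two-letter
code is uppercase only when both ends belong to the same target locus.
Overlaps between loci resolve T over A, then the nearer capture span.

## Filters and VAF (filter)

Filters apply in a fixed order (MAPQ, size, target class, shared
endpoints, family size, read pairs, duplex, molecules, samples) with an
attrition count per predicate. Defaults reproduce the high-confidence
setting: MAPQ ≥ 50 per flanking alignment, at least three read pairs,
detection in a single co-analyzed sample. `min_read_pairs` counts read
pairs summed over strands of the best-supported molecule — read pairs,
not source molecules — which is what separates chimeric PCR (family size
one) from replicated true molecules. Shared-endpoint exclusion drops a
call only when every supporter is flagged, since a true SV can coexist
with one recombined artifact template. A duplex molecule counts once
toward `n_molecules` (one source fragment), and outer-clip recoveries
count toward both `n_molecules` and VAF support.

Coverage is the summed overlap of unique proper-molecule spans with the
capture spans divided by the total capture length — molecules per base,
not read pairs. VAF is per-sample supporters over per-sample coverage.

## Genotypes and junction-proximal variants (genotype, stats)

Proper-molecule consensus bases are piled up over the targets and
adjacent regions; positions with at least 10 unique molecules keep up to
two alleles at fraction ≥ 0.2 (more than two well-supported alleles marks
the position uncallable and uninformative). These thresholds are this
package's internal genotyper settings; a VCF of known genotypes can be
imported instead. Junction-consensus columns (cross-molecule majority
with the same 2/3 rule) that differ from the reference and are absent
from the haplotype allele set are de novo SNVs (consensus gaps: indels).
Distances are measured from the first non-microhomology base — distance 1
is adjacent to the junction — and microhomology columns themselves are
skipped as side-ambiguous.

The proximity test draws `n` distances from the distribution weighted by
how many variant-containing SV flanks cross each informative distance,
over 10 000 iterations; `p` is the fraction of iterations whose median is
strictly below the observed median (ties are non-exceedances, per the
one-sided proximity alternative). A `+1/(N+1)` finite-sample correction is
available as an option, and a Mann–Whitney rank test on raw distances is
offered as a secondary check. Weighting by flank crossings (rather than
per informative base) follows the definition of the expected distance
distribution; the per-base alternative would differ only when flanks have
internal coverage holes.

## The simulator

The generator defines the study conditions: a small multi-chromosome
genome (default three 200 kb chromosomes) with one central capture target
per chromosome and adjacent flanks — the capture-design geometry scaled
down — a clone mixture with heterozygous Del/Dup SVs planted at exact
breakpoints and exact junction metrics (homology tracts are engineered
into the reference and verified at plan time), fragment sizes
N(300, 40²) as for sonication to a 300 bp peak, 2×151 reads, 1% per-base
substitution error, and per-strand read-pair families drawn from a
zero-inflated Poisson (π = 0.3, λ = 1.0; conditioned on at least one read
pair overall) giving a conditional duplex fraction of about 0.28.
Capture enrichment is an acceptance probability by fragment overlap class
(T 1.0, A 0.3, other 0.002), exposing the reduced recovery of junctions
with only one captured end.

Artifact classes are generated with their mechanistic signatures:

* *Ligation chimeras* join a captured fragment to a second fragment drawn
  uniformly from the genome before strand assignment, so both strands
  carry the junction and the molecule can be duplex; junctions are blunt
  or a single-base insertion that is A/T with probability 0.81.
* *Chimeric PCR* events template-switch at a planted shared k-mer (k
  peaked at 8–9) after strand assignment: always one strand, one read
  pair, sharing one outer endpoint with an explicitly emitted proper
  template molecule. Switches occur in either orientation, so chimeric
  junctions appear as all four SV types.
* *Foldback* artifacts (tagmentation mode only) are sub-kilobase
  inversion junctions with large planted homology.

The emulated aligner is idealized: split placements are
upstream-maximal, isolated clipped alignments extend maximally into
matching reference (decided on the error-free template, so isolated
sequencing errors appear as mismatches without moving breakpoints), and
MAPQ is constant (60) apart from a configurable low-MAPQ fraction —
alignment error, whose published remedy is MAPQ filtering, is modeled
only through that dial. Distinct artifact junctions are planted at least
one insert-size apart (foldbacks excepted, as dense local hairpins), a
spacing the real 250 kb-scale design provides naturally but a scaled-down
genome must enforce, since the assembly stage is entitled to assume that
independent artifact events do not share a junction neighborhood.

What passing simulator-based tests does *not* show about real data:
alignment ambiguity in repeats, reference bias, indel-rich junctions,
base-quality structure, GC-dependent capture efficiency and
clone-mixture pipetting error are all absent. The simulator's VAF
calibration therefore isolates pipeline-intrinsic losses (sub-threshold
clips, duplicate purging, clip-match failures), which bias recovered
VAFs a few tenths of a percentage point below the heterozygous
expectation.

## Problem sizes

The bundled validation suites run on deliberately small instances chosen
to keep the full test run in minutes: artifact-behavior suites use
3×12 kb targets at 300× molecule coverage (about 250 artifact junctions
per class), and the VAF calibration uses 3×12 kb targets at 2000×
coverage with 24 heterozygous deletions in a 10% clone, matching the
published sequencing depth while scaling the captured territory.

## Known limitations

* Chained molecules with three or more junctions contribute each adjacent
  node pair independently; no joint phasing of multi-junction molecules.
* Insertion-type SVs (novel sequence longer than `min_sv_size`) are out
  of scope; de novo junction inserts are reported but not called as SVs.
* The genotype stage requires collate output from the same run; only the
  filter stage can restart from a previous run's tables.
* CRAM input is not handled (reference-dependent decoding is
  environment-specific); SAM/BAM are.
* De novo indel detection is limited to consensus deletion columns;
  inserted bases within flanks are not scanned.
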