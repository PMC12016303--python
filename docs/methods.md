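# Methods

## Model and scope

`tprt-detect` treats a candidate insertion as a putative product of
target-primed reverse transcription (TPRT) and asks three questions: what
element family produced it, which TPRT hallmarks does it carry, and is it
somatic or germline within a cohort. The unit of analysis is one
Sniffles-style insertion call (the full inserted sequence plus its
reference position); deletions whose breakpoints fall within 50 bp of an
annotated reference TE are carried along as polymorphic reference
elements. All internal coordinates are 0-based half-open; the 1-based VCF
convention is converted only in `io_formats`.

## Junction placement

Hallmark detection starts from the placement of the two insertion
junctions on the reference. The locus haplotype — a majority-vote
consensus of the supporting reads when reads are available, otherwise the
VCF sequence embedded in its reference flanks — is anchored on the
reference and extended base by base from each side. The reference
coordinate where the left-flank extension stops is `left_bp`; symmetric
from the right gives `right_bp`; the sequence between them is the
insertion. `left_bp − right_bp` in [5, 25] is a target site duplication
(both flanks covered the duplicated bases), the negated difference in the
same window a target-site deletion. Extension crosses an isolated
mismatch only when the following 20 bases match at ≥ 90% (a residual
consensus error in a flank), which keeps the junction exact on clean
sequence — insertion content is unrelated to the reference, so the bridge
test cannot fire at a true junction.

A consequence worth stating: a bare VCF INS record cannot encode the
bases removed by a target-site deletion, so TS deletions are only
recoverable when supporting reads (or the locus haplotype) are provided.
Duplications are recoverable either way, because the duplicated bases are
present inside the VCF ALT sequence.

## Consensus polishing

Reads supporting one locus are polished by iterated majority vote (two
rounds by default): the longest read is the backbone, every other read is
infix-aligned to it with edlib and votes per column, and the second round
realigns all reads against the first-round consensus, which clears vote
ties caused by backbone errors. Edge columns covered by fewer than
max(2, n/3) reads are trimmed — only the longest read spans them, so
their errors are uncorrectable and would derail junction placement. The
polisher is substitution-oriented (read insertions relative to the
backbone are ignored), matching the simulator's error model; a different
polisher can be substituted wherever a list of reads is accepted.

## Family classification and segment mapping

Insertions are aligned against every library consensus on both strands
using exact k-mer (k = 13) anchor chaining refined with edlib infix
alignment (`align.map_segments`). The best-scoring entry passing identity
≥ 0.8 and query coverage ≥ 0.5 (polyA excluded) assigns family and
subfamily; ties break by identity, then name. The element strand is the
orientation of the polyA-proximal segment — for twin-primed insertions
the inverted segment would otherwise flip the call. A sequence with no TE
hit but a terminal polyA tail is an `orphan` (candidate orphan
transduction); non-TE, non-orphan sequences of ≥ 200 bp are tested
against the cDNA library for processed-pseudogene content, with TE
classification taking precedence.

## Hallmark detectors

**polyA.** The longest suffix that starts and ends in A with A-purity
≥ 0.8 and length ≥ 10 bp. The leading-A requirement is this package's
refinement of a plain purity rule: without it, any A-tail creeps into the
element body one non-A base at a time (a suffix of k A's plus one non-A
still has purity k/(k+1)).

**TSD / TS deletion.** Directly from the junction placements as above;
window 5–25 bp inclusive on both ends.

**EN cut site.** The first-strand nick is taken at the junction adjacent
to the element polyA (`right_bp` for plus-strand insertions, `left_bp`
for minus). The motif is read on the strand on which the T-tract lies 5'
of the nick: for a plus-strand insertion that is the reverse strand, so
TTTT/A corresponds to a genomic A-tract immediately downstream of the
junction — the tract the element's polyA annealed to. Motifs scored:
TTTT/A, TTTT/G, TTTC/A, exact match only; shifted or mismatched motifs
count as absent.

**Transduction.** Non-TE sequence 3' of the element (or the whole body of
an orphan) is mapped to the reference; the placement must be unique (best
locus beating all rivals by a margin, the MAPQ > 10 proxy) and fall
within 3000 bp downstream of the 3' end of a registered full-length
element.

**Full length.** L1 calls whose total consensus-aligned length exceeds
5990 bp.

TPRT-family calls (L1/Alu/SVA/PP) carrying none of {polyA, TSD or TS
deletion, EN motif} are removed; other families pass unconditionally.

## Twin priming

Criteria are evaluated in order and the first match reported: (1) two
consensus-mapped areas of opposite orientation; (2) one consensus area
plus one uniquely reference-mapped area of opposite orientation; (3) two
uniquely mapped areas in opposite orientation within 500 bp of each other
on the reference. Minimum mapped area: 30 bp. For L1 (criterion 1) calls
both cDNAs are realigned to the L1 consensus; spans are stored ascending,
`noninverted_span = (b, L)` for the polyA-primed cDNA and
`inverted_span = (a, c)` with `c` the internal priming point.

`junction_distance = b − c`: positive means a consensus interval was
reverse-transcribed into neither cDNA (a gap), negative that the interval
`[b, c)` is present in both (an overlap), so the magnitude of a negative
distance literally equals the length of the shared consensus sequence.
Criterion-3 calls (e.g. inverted processed pseudogenes, whose natural
coordinate system is their cDNA) report segment lengths but no consensus
spans. The polyA tail is excluded from all spans and lengths.

## Cohort classification

Merging is single-linkage over calls of identical SV type and strand with
neighbor distance ≤ 50 bp; the merged position is the highest-support
call's (leftmost on ties). A locus is a somatic candidate iff its only
carrier is a single tumor sample and no call from any other sample — TE
or not — lies within 10 bp (inclusive; the boundary is configurable). The
type-based filter computes, per family, the expected number of singleton
germline events surfacing as somatic
(`unique germline count / germline samples × tumors without normal`) and
excludes the family when that expectation reaches the observed count;
expected counts are kept real-valued so the decision never depends on a
rounding rule. Known-polymorphism flagging requires a table entry of the
same TE type within 300 bp.

## Read support

Each insertion becomes a single-bubble graph: ~2000 bp flank nodes (
truncated and flagged at contig ends), an insertion node, and a reference
path. The bundled aligner maps each read to both linear path sequences
with edlib and keeps the better, which is equivalent to graph alignment
for a single bubble. A read supports the insertion path iff it overlaps a
flank node and the insertion node for ≥ 50 nt each, and the reference
path iff its span encloses the 50 nt on either side of the reference
junction; a read counts for at most one path. Nanopore evidence in a
normal sample counts insertion-bearing reads within a factor of two of
the call length and 100 bp of the position, plus soft clips > 30 bp
ending within 10 bp. The Illumina proxy counts pairs within 100 bp of the
breakpoint whose mate maps to another chromosome or > 600 bp away; both
the ≥ 4-read count rule and the ≥ 10% ratio form are available, the count
rule being the default curation channel. The automatic curation rules:
< 3 tumor supporting reads → false positive; any normal evidence (≥ 1
nanopore read or ≥ 4 discordant pairs) → germline; a clean nanopore
normal, or a clean Illumina normal at ≥ 40× depth, certifies true
somatic; otherwise unclassifiable.

## Statistics

* Relative insertion rate:
  `log2(((hits+1)/(total+1)) / ((target_bp+1)/(ref_bp+1)))`.
* Bootstrap CIs (default R = 10 000, percentile, seeded) resample
  insertions' hit/miss labels with the genomic denominators fixed;
  resampling target bases instead was the open alternative, but
  insertions are the sampling unit of the experiment.
* Rectangular KDE: `density(x) = (1/(n·2h)) Σ 1[|x−xi| ≤ h]`, evaluated
  on a grid containing every box edge (± 1e-9) so trapezoid integration
  is exact to ~1e-9. Bandwidths follow the figures they feed: 40 bp for
  insertion-length densities, 10 bp for within-element profiles.
* Within-element profiles use only reference copies whose length lies in
  the family's canonical window (mode ± 10%: L1 5531–6761 bp, Alu
  281–343 bp); AT content is averaged per consensus position over those
  copies and smoothed with a centered rolling mean, k = 10.
* Replication-timing comparisons use Welch's unequal-variance two-sided
  t-test (the plain "two-sided t-test" is underspecified; Welch is the
  safe default); identical degenerate groups report t = 0, p = 1 with a
  flag.
* 2x2 chi-square tests use **no continuity correction**: the published
  twin-priming comparison (328/1495 vs 165/897 → p = 0.038) reproduces
  only without Yates correction (0.043 with). Percentages are rounded
  half-away-from-zero at the table's precision.

## The simulator: what it does and does not emulate

`tprt_detect.sim` builds a random reference (default 400 kb; 1 Mb for the
large recovery experiment) with planted consensus copies — full-length
and 5'-truncated L1s (reproducing the reference 3' bias), Alus within the
canonical length window, SVA/ERV copies, simple and low-complexity
repeats — plus genes whose spliced transcripts form the cDNA library, a
smooth replication-timing track, and a registry of full-length elements
with transducible downstream blocks. Events are placed ≥ 1.2 kb apart;
EN-motif bases are written into the reference at each nick before
haplotypes are built. Default study conditions: 8 samples (3 tumors),
heterozygous carriers, depth 8 (20 in the noisy experiment), polyA
lengths 15–60 bp, TSDs sweeping the full 5–25 bp window, all three EN
motifs plus motif-free sites, twin-priming geometries with gaps and
overlaps (junction distances −25…+40 bp), 300 bp transductions, and
orphan/pseudogene/ERV/non-TE events.

Two idealizations make *exact* recovery testing meaningful, and bound
what passing tests say about real data:

1. **Junction-base guarantees.** The reference base adjacent to each
   junction is constrained to differ from the neighboring cassette base,
   so flank extension stops exactly at the planted breakpoint. Real
   genomes have no such guarantee; microhomology at junctions shifts
   breakpoints by a few bases and makes TSD lengths ambiguous at the
   ±1–2 bp level.
2. **A-sparse 3' termini.** Consensus, cDNA and transducible-block 3'
   ends carry no A in their last 15 bases, making the polyA boundary
   unambiguous. Real L1 3' UTRs end A-rich, and nanopore homopolymer
   errors blur tail lengths further — exact polyA-length recovery is a
   property of the generator's conditions, not of real reads.

The error model is i.i.d. substitutions (default 0; 5% in the noisy
experiment). No indels, no homopolymer compression, no chimeras, no
mapping ambiguity from diverged subfamily copies. Under substitutions at
5% with depth 20, family and somatic-status recovery stays ≥ 95%;
hallmark-exact recovery is only asserted error-free.

## Problem sizes and runtime

The default test suite runs one 30-event error-free cohort, one 25-event
noisy cohort and one ~200-event error-free cohort (1 Mb reference, 10
samples); the full suite completes in well under a minute, and the
acceptance script in ~20 s on one CPU. These sizes were chosen as the
smallest that exercise every family, hallmark, criterion and filter
simultaneously.

## Known limitations

* Subfamily assignment is whatever the library provides; no phylogenetic
  subfamily calling.
* The twin-priming detector reports the first satisfied criterion only;
  precedence among criteria is a design choice (paper order 1→2→3).
* Criterion-3 inversion calls carry no consensus spans.
* The VCF-only annotation path cannot see TS deletions (above).
* The discordant-pair and nanopore-evidence functions consume abstracted
  read records, not BAMs; extracting those records from arbitrary
  aligners is out of scope.
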