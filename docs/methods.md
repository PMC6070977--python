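# Methods

## The detection model

`segf` treats fusion detection as a split-read problem with the split chosen
by the caller, not by an aligner. A DNA fusion joins two genomic regions; a
read spanning the junction fails full-length alignment, and general-purpose
aligners recover it only through soft-clipping, which is fragile when the
junction carries extra sequence. `segf` instead pre-splits every read into a
**paired soft-clipped contig (PSC)**: after trimming `trim_len` bases from
both ends, the first and last `remain_len` bases of the remainder (head and
tail) are kept as a tracked pair and the middle is discarded. For the
default 151-bp read, head = bases [10, 45) and tail = bases [106, 141); the
61-base middle — which contains the junction and any inserted linker — is
never examined.

Each segment is screened through two exact searches:

* **target search** — all exact full-length occurrences in the panel genes'
  sequences, either strand;
* **genome search** — occurrences in the whole genome, where the segment
  must be *unique* (exactly one occurrence counting both strands and all
  chromosomes).

A segment is accepted as evidence only when it is genome-unique, hits a
target gene with 100% identity, and its unique genomic coordinate lies
inside that gene's interval (the coordinate cross-check between the two
searches). A read whose head and tail evidence name two different genes
contributes one observation to that unordered gene pair; pairs with at
least `min_support` distinct supporting reads become calls. Intra-gene
(same-gene) pairs are never called. Head/tail strand and orientation are
recorded in the evidence but not used as a filter.

### Why exact matching replaces BLAST/SOAP

The original formulation runs a local aligner against the target set and a
short-read mapper against the genome, then discards every hit that is not
full-length, gapless, mismatch-free — and, on the genome side, not unique.
Under those filters the surviving hit set is *exactly* the exact-match set,
so the package implements one strand-aware exact-occurrence index (a hash
table over forward-strand k-mers; minus-strand queries answered via the
reverse complement) and uses it in both roles. This removes two heavyweight
external dependencies, makes behaviour bit-reproducible, and lets an O(n·k)
brute-force scan serve as an independent oracle in the tests. One
deliberate strictness: a palindromic segment matching one locus on both
strands counts as two occurrences and is classified multi-mapping. We do
not mask low-complexity queries; a homopolymer segment simply fails the
genome-uniqueness filter in any realistic genome.

### The PSC as a pair, not a 70-mer

The head and tail are aligned independently and tied together by read id.
A concatenated 70-mer could never survive a full-length 100%-identity
search across a fusion junction, so pairing is the only reading under which
the stated filters can produce fusion calls; fusion evidence is defined as
the two segments of one read hitting two different panel genes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `trim_len` | 10 bp | bases cut from each read end; sequencing quality is poorest in the first and last ~10 cycles, and trimming them keeps end errors out of the exact-match segments |
| `remain_len` | 35 bp | segment length = index k. Long enough that a random 35-mer is unique in a human-scale genome (4^35 ≫ 3·10^9), short enough to leave junction room in a 151-bp read; adjustable for other read lengths |
| `min_support` | 3 | distinct reads required per gene pair ("more than two"); support counts read ids, so identical duplicate molecules with distinct ids each count unless `--dedup-psc` is set |
| `--dedup-psc` | off | drop duplicate (head, tail) sequence pairs before screening |

A read shorter than 2·(`trim_len` + `remain_len`) = 90 bp is skipped
(counted, not an error): padding would violate the 100%-identity contract.
Segments containing N are likewise skipped early — they can never match
exactly.

## The simulator

`simulate` builds hermetic test worlds: uniform-random DNA chromosomes
carrying the 14 panel genes as disjoint intervals (default three
chromosomes, 1000-bp genes, 300-bp intergenic gaps; the test suite uses
300-bp genes with 200-bp gaps). Reads are 151 bp, single-end. Fusion-
supporting reads are drawn uniformly over junction-spanning placements that
keep both 35-mer segments wholly inside the two partner genes, so every
planted read is in principle detectable and recovery tests are sharp;
"complex" specs insert a linker (such as the 48-bp engineered insert
observed between *ALK* and *EML4* in commercial reference standards) at the
junction. Wild-type reads are drawn uniformly from either strand of the
genome. Substitution noise (default 2% per base) is confined to the first
and last 10 cycles — the same cycles the pipeline trims — mirroring the
end-degraded quality profile that motivates trimming while keeping the
interior error-free, so the behaviour of the 100%-identity filter stays
analyzable.

What the simulator does **not** emulate: FFPE damage chemistry (deamination
spectra), capture-efficiency and GC bias, PCR duplicates, paired-end
insert-size structure, interior sequencing errors, and the repeat content of
a real genome (uniform-random DNA makes spurious exact 35-mer repeats
vanishingly rare). Passing recovery tests therefore demonstrate the
algorithm's behaviour under its own model — junction-spanning coverage with
clean interiors — not its sensitivity on degraded clinical libraries, where
library quality and input mass dominate.

One geometric caveat at desk scale: intergenic gaps must exceed the span
between head start and tail end within a read (131 bp at defaults),
otherwise a single wild-type read can straddle two neighbouring panel genes
and fake fusion evidence. Real panel genes are megabases apart; the
simulator's default 300-bp (and the tests' 200-bp) gaps respect this bound.

## Evaluation arithmetic

`evaluate` computes sensitivity = 100·TP/(TP+FN), specificity =
100·TN/(TN+FP) and positive-detection rate = 100·TP/total with exact
rational arithmetic (`fractions.Fraction`), rounding half-up to two
decimals only for display; a statistic whose denominator is zero (e.g.
specificity of an all-positive reference-standard cohort) is reported as
absent and rendered "-". Sample-level comparison is pair-scoped: a sample
counts as called only if its call set contains the specific gene pair under
evaluation, so calls for other pairs do not inflate false positives.
Dilution arithmetic divides a nominal fusion frequency by the dilution
factor (5% diluted 12-fold → 0.42%).

## Numerical and design choices

* **Coordinates** are 0-based half-open everywhere; the bundled panel
  fixture was converted from 1-based inclusive once at packaging time.
* **Annotation anchor**: the genomic start of a 35-bp segment decides its
  intron/exon label; a segment straddling an exon boundary is invisible by
  construction. Call-level labels are the majority over supporting
  segments, with exact ties reported as `mixed`.
* **Target set**: gene sequences are kept as a named set rather than one
  concatenated reference, so target hits carry gene identity without
  breakpoint bookkeeping across artificial joins.
* **Panel disjointness** is asserted at load time; it guarantees a
  genome-unique segment belongs to at most one gene.
* **Tie-breaks and ordering**: hits sort by (reference, position, strand);
  calls by (descending support, gene pair); outputs are byte-deterministic
  for fixed inputs, options and seed.
* **Paired-end input** is consumed as two independent single-end streams;
  read ids are suffixed per stream so mates sharing a header can never be
  cross-paired into one chimeric observation.

## Problem sizes

The test suite and the acceptance script run the full pipeline on synthetic
genomes of ~5–8 kb (14 genes × 300 bp, 200-bp gaps, three chromosomes) at
depths of 500× (recovery, fractions 1–20%) and 5000× (low-fraction
detection at a 0.42% fusion fraction, ~190,000 reads per replicate), with
10–20 independent seeds per experiment. The aligner is validated against a
brute-force both-strand scan on random genomes up to 100 kb with 1000
35-mer queries each. Study-condition parameters (151-bp reads, trim 10,
keep 35, support ≥ 3) are used unchanged throughout.

## Known limitations

* Breakpoints are deliberately not resolved to base precision; calls name
  gene pairs, not junction coordinates.
* Fusions whose junction-proximal 35-mers fall in repetitive or shared
  sequence are rejected by the genome-uniqueness filter.
* A fusion read must carry ≥ `trim_len` + `remain_len` = 45 bp of each
  partner gene; junctions closer than that to a read end are invisible in
  that read.
* Support is not an allele-fraction estimate: without duplicate removal it
  scales with depth and library duplication.
* The threshold wording in the source material is ambiguous ("more than
  two reads" vs "larger than three"); the package follows the former
  (≥ 3) and exposes `--min-support`.
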