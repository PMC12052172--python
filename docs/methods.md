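# Methods

## Problem and model

Rolling-circle amplification of a circular DNA template produces a linear
concatemer: a read of *p* passes covers the circle *p* times in tandem.
Aligned to a linear reference, such a read decomposes into blocks with two
diagnostic patterns: (i) adjacent read blocks that join
reference-discontiguous loci (a **breakpoint**, present once per circle
junction per pass), and (ii) repeated traversal of the same reference locus
in the same orientation (**circular template concatenation, CTC**, present
whenever p ≥ 2). `ecclong` reconstructs circles from these patterns alone;
it never assembles de novo.

Coordinates are 0-based half-open everywhere (internally, in BED, and in
PAF, which natively uses that convention).

## Read classification

A PAF row becomes an alignment block; blocks of one read overlapping in
read coordinates are resolved by keeping the higher-mapq block and
truncating the other (ties: the longer block wins), so profiles are
non-overlapping and read-ordered. Reads failing any floor — mean base
quality < 10 (when known; carried in an `rq:f:` PAF tag by the simulator,
absent from aligner PAFs), aligned fraction < 0.3, length < 200 bp — are
ghosts and excluded.

A read is **ctc** when either
(a) two blocks at different read positions cover the same reference
interval in the same orientation — reciprocal overlap ≥ 0.8 *and* both
boundaries within 50 bp (`same_locus_tolerance`) — or
(b) ≥ 80% of the read's reference footprint is covered ≥ 2 times in the
same orientation.
Rule (b) catches exact-two-pass concatemers whose rotation splits every
copy into partial blocks that fail the pairwise test; rule (a) catches
multi-fragment concatemers in which only a short fragment repeats. With
both rules, every error-free read with p ≥ 2 is ctc, and reads with
p < 1.5 from single-fragment circles never are (for asymmetric
multi-fragment circles a sub-1.5-pass read can genuinely contain two full
copies of its shortest fragment — that is real tandem evidence, not a
false positive). A read that is both ctc and breakpoint is reported ctc:
circularity evidence dominates. Otherwise a read with any non-colinear
adjacent block pair is **breakpoint**; colinear means same chromosome and
strand with the reference gap matching the read gap within 50 bp.

**CTC trimming** walks the blocks in read order keeping each block's novel
reference portion (clipped when partially repeated); it stops at the first
block that is repetition within tolerance, absorbing a sub-tolerance novel
remainder so the retained pass covers the circle exactly once. The sum of
retained reference spans is the implied circle length. Trimming is
idempotent (trimmed profiles carry a flag and pass through unchanged).

## Circle calling

Blocks of breakpoint and trimmed ctc reads are merged per chromosome by
sort-and-sweep (touching or overlapping intervals merge; `merge_gap` ≥ 0
widens the rule). Normal reads are excluded from region building: their
blocks carry no junction evidence, and chains of overlapping background
reads would otherwise fuse distinct circle loci into one region, which the
one-circle-per-region rule below would then mis-arbitrate.

Each non-colinear adjacent block pair (and, for ctc reads, the wrap-around
pair last→first unless it merely continues the same locus) emits a
junction between two region *flanks*: traversing a region forward enters
its left (low-coordinate) flank and exits its right flank; minus-strand
traversal swaps them. Junctions with the same flank pair and offsets
within `junction_tolerance` (20 bp) aggregate into a linkage with summed
read support. The flank formulation makes A→B and B→A traversals of the
same junction identical, and makes foldback junctions (same flank twice)
ineligible for circles.

Regions are nodes, linkages ≥ `min_support` (default 2: one chimeric read
must not call a circle) are edges of an undirected multigraph. Candidate
circles are all orientation-consistent realizations of the graph's simple
cycles — including self-loops (single-fragment circles) and parallel-edge
2-cycles — enumerating every edge choice so that parallel linkages compete
on support. Candidates are ranked by total support (ties: smaller genomic
coordinate) and selected greedily, each region and edge in at most one
reported circle.

For each selected cycle, fragment boundaries are the median junction
offsets on each flank; the call's sequence concatenates the fragment
reference sequences in cycle order, reverse-complementing minus-strand
fragments. Reporting uses a canonical rotation: start at the
lexicographically smallest (chrom, start) fragment, forward orientation.
`n_reads` counts distinct reads supporting any edge; `mean_depth` is
aligned bases of those reads (untrimmed, so every pass counts) inside the
fragments divided by circle length — a fold-coverage. A call is **simple**
if one chromosome contributes all fragments, else **complex**.

## Annotation and statistics

Composition intersects each call with interval tracks (gene, exon, intron,
5'/3' UTR, CpG, SINE, LINE, LTR, other_repeat), ignoring strand; a feature
split across fragments counts once per call, while overlap bases are
summed. Both counts and bases are reported, as the natural units differ by
question; per-group aggregates add the intron:exon count ratio.

Statistics are pure functions of their inputs: size quantiles and the
below-3-kb fraction; eccDNA count per million reads (denominator:
quality-filtered reads by default, switchable to raw); per-chromosome
densities as count / (length in Mb), assigning each call to its canonical
fragment's chromosome and flagging extra chromosomes of complex calls
separately so neither reading of multi-chromosome circles is lost; the
MssI/PmeI site census (5'-GTTTAAAC-3', a perfect palindrome, scanned with
overlaps and circularly by extending the sequence with its first 7 bases —
forward and both-strand modes coincide for palindromes, and N never
matches); binned coverage (aligned bases per bin / bin width, bin size 10)
with RPGC normalization rescaling the genome-wide mean to exactly 1×
(partial terminal bins are width-weighted, so the identity is exact);
and per-gene mean depth summed across replicates within each group, with a
pseudocount of 1 keeping zero-coverage ratios finite. "Extend reads" has
no meaning for fully aligned long-read blocks, so coverage uses exact
block spans — an intentional deviation from short-read practice.

## The simulator

The generator emulates the statistical structure the pipeline assumes, not
nanopore physics. Defaults define the study conditions used throughout the
tests:

| parameter | default | rationale |
|---|---|---|
| genome | 5 × 400 kb, GC 0.41 | multi-chromosome so complex circles exist; desk-scale |
| circles | 20 simple + 5 complex, 300–8000 bp | typical size span of cell-line eccDNA below the megabase ecDNA regime |
| complex fragments | 2–4, ≥ 2 chromosomes, ≥ 100 bp | minimal multi-fragment structure |
| circle spacing | ≥ 20 kb | background reads (≤ 15 kb) cannot bridge two circles into one region |
| mito-like circle | 16.5 kb contig `chrM_sim` | mtDNA-scale target for depletion tests |
| passes per read | geometric, mean 4, capped at 90 kb reads | no published pass distribution; nanopore Circle-Seq libraries reach high-tens-of-kb read lengths |
| reads per circle | 10 | enough that min_support 2 is nearly always met |
| errors | 1% substitution, 0.25% + 0.25% indel | i.i.d. per base; stresses junction tolerance |
| base quality | Normal(20, 4), clipped 2–41 | above the filter floor of 10 |
| enzyme model | MssI: removes mito + every site carrier; Cas9: removes mito with prob 0.86 | the published Cas9 mtDNA-depletion efficiency is ~0.86 |

Circles are planted uniformly (chromosome ∝ length) and non-overlapping;
the restriction site is written into the genome inside a fragment for the
requested fraction of circles, and every circle's site flag is then set by
scanning its actual circular sequence, so chance occurrences are flagged
too. Reads start at a uniform rotation, copy the circle tandemly for the
drawn (possibly fractional) pass count, are reverse-complemented with
probability ½, and receive the alignments an ideal aligner would report
("truth PAF"), with block splits at fragment boundaries and pass wraps.

What the simulator does **not** model — and hence what passing tests do not
show about real data: homopolymer-biased or context-dependent errors;
reference-coordinate jitter from a real aligner (truth-PAF reference spans
are exact even under read errors; only read coordinates shift with
indels); chimeric ligation artifacts; mappability/repeat ambiguity (the
random genome is effectively unique); RCA branch structures beyond linear
concatemers; and any depth bias along the circle. The quality floors,
tolerances and the support threshold are exercised, but their real-data
operating points will differ.

## Numerical and degenerate-input choices

Median junction offsets are rounded to integers; if refinement inverts a
fragment (start ≥ end, possible only with contradictory junctions) the raw
region bounds are used. Empty inputs return empty outputs except where a
contract forbids them: a PAF with zero usable rows, RPGC on an empty track,
and per-million with zero reads raise with explicit messages. All
randomness flows through `numpy.random.default_rng(seed)`; every generator
and every statistic is deterministic given parameters, and an end-to-end
run is byte-reproducible given seed + configuration.

## Known limitations

Circles sharing a region are arbitrated greedily rather than jointly
resolved; inverted-duplication (foldback) reads are labeled breakpoint,
never ctc, and foldback-only structures are not called; junction refinement
uses median offsets, not consensus realignment; calling from short reads
and de-novo assembly are out of scope. The verification experiments use
planted, well-separated circles at modest depth (sizes chosen so the whole
suite runs in well under a minute per experiment on one CPU); performance
on real libraries with overlapping or nested circles is not characterized.
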