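# ecclong

Detection and characterization of **extrachromosomal circular DNA (eccDNA)**
from long-read Circle-Seq alignments, with a ground-truth rolling-circle
read simulator.

eccDNAs are chromosome-derived circular DNA elements present in normal and
cancer cells; in tumors they can carry and amplify oncogenes. Circle-Seq
enriches them by exonuclease digestion of linear DNA, depletion of
mitochondrial DNA (MssI/PmeI restriction or Cas9 cutting) and rolling-circle
amplification (RCA) with Phi29 polymerase. A long read sequenced from an RCA
product contains *tandem copies* of its template circle — the defining
signature of circularity. `ecclong` exploits that signature:

1. **Read classification** — PAF alignments are collapsed into per-read block
   profiles; reads are labeled **normal** (contiguous alignment),
   **breakpoint** (adjacent blocks join reference-discontiguous loci), or
   **CTC** (circular template concatenation: the same locus is traversed two
   or more times in the same orientation). CTC reads are trimmed to exactly
   one pass of their circle. Ghost reads (unalignable or below quality
   floors) are removed first.
2. **Circle calling** — retained junction-evidencing blocks are merged into
   genomic regions; breakpoint junctions become linkages between region
   flanks. Regions are nodes and linkages are edges of a breakpoint graph;
   every orientation-consistent simple cycle whose edges each have
   ≥ `min_support` reads is a candidate circle, and a greedy support-ranked
   selection assigns each region to at most one circle. Fragment boundaries
   are refined to the median junction offset over supporting reads, and the
   circle sequence is extracted from the reference (reference-guided
   assembly), with a canonical rotation/orientation for reporting.
3. **Annotation & characterization** — per-call feature composition (exon,
   intron, UTRs, CpG, SINE/LINE/LTR), size distributions and the <3 kb
   fraction, counts per million reads, per-chromosome densities (count per
   Mb), a census of the MssI recognition site 5'-GTTTAAAC-3' (scanned
   circularly, so origin-spanning sites are found), RPGC-normalized binned
   coverage tracks, and replicate-summed per-gene depth contrasts between
   groups.
4. **Simulation** — a synthetic genome with planted annotation, simple
   (single-fragment) and complex (multi-fragment, multi-chromosome) circles
   of 300–8000 bp, a 16.5 kb mitochondria-like circle on its own contig,
   concatemeric reads with geometric pass counts, substitution/indel errors,
   linear background and ghost reads — plus the alignments an ideal aligner
   would report, so the whole pipeline is testable without downloads.

## Worked example

```sh
ecclong demo --outdir demo_run --seed 42
```

simulates the default study (20 simple + 5 complex circles on a 5 × 400 kb
genome, 10 reads per circle, mean 4 passes, 1% substitution / 0.5% indel
errors, 200 linear background reads), runs every stage and prints:

```json
{
  "complex_fraction": 0.2,
  "ecc_per_million_reads": 55555.555555555555,
  "fraction_below_threshold": 0.32,
  "intron_exon_ratio": 0.75,
  "n_calls": 25,
  "n_calls_with_mssi_site": 9,
  "reads": {
    "breakpoint": 46, "ctc": 204, "normal": 200,
    "ghost_filtered": 0, "ghost_unaligned": 0,
    "retained": 450, "total": 450
  },
  "simple_fraction": 0.8
}
```

All 25 planted circles are recovered (`n_calls`), with the planted 20:5
simple:complex split (`simple_fraction` 0.8), the planted size mix below
3 kb (`fraction_below_threshold`), and 55,556 eccDNAs per million retained
reads (25 × 10⁶ / 450). The run directory contains the genome FASTA (+ .fai),
annotation GFF3/BED, reads FASTQ, truth PAF and circle manifest, per-read
labels, calls as BED + manifest TSV + FASTA sequences, composition and
statistics TSVs, an RPGC coverage bedGraph, a summary JSON and a checksum
manifest. `ecclong run --paf aln.paf --fasta ref.fa` runs the same stages on
real aligner output (e.g. minimap2 PAF) instead of a simulation.

Library use mirrors the CLI: `generate_genome`, `sample_circles`,
`simulate_reads`, `load_alignments`, `filter_reads`, `classify_read`,
`trim_ctc`, `call_all`, `annotate_call`, and the statistics functions are
all importable from `ecclong`.

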