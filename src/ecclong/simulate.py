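"""Synthetic Circle-Seq data with full ground truth.

Emulates the statistical structure a long-read eccDNA pipeline assumes:
a small multi-chromosome genome, planted simple (single-fragment) and
complex (multi-fragment, multi-chromosome) circles, rolling-circle
amplified concatemeric reads with variable pass counts, a linear-DNA
background, unalignable ghost reads, a mitochondria-like circle on its
own contig, and an enzymatic mtDNA-depletion model (MssI restriction or
Cas9 cutting).

Every generator is a pure function of its parameters and seed; identical
calls produce byte-identical outputs.  The simulator also emits the
alignments an ideal aligner would report ("truth PAF"), including the
block splits at circle breakpoints and pass wrap-arounds, so the
downstream pipeline is testable without an external aligner.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _seq
from .annotate import AnnotationTrack

MSSI_SITE = "GTTTAAAC"  # MssI/PmeI recognition sequence, a perfect palindrome
MITO_CHROM = "chrM_sim"
MITO_LENGTH = 16_500
MIN_FRAGMENT = 100

__all__ = [
    "GenomeRef",
    "TruthCircle",
    "SimRead",
    "SimReadSet",
    "generate_genome",
    "plant_annotation",
    "sample_circles",
    "circle_sequence",
    "simulate_reads",
    "apply_enzyme_model",
    "DEFAULT_FEATURE_CONFIG",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeRef:
    """A reference genome held in memory: chromosome name -> sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("chromosome names must be unique")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        try:
            seq = self.sequences[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None
        if not (0 <= start < end <= len(seq)):
            raise ValueError(f"invalid span {chrom}:{start}-{end} (length {len(seq)})")
        return seq[start:end]

    def gc_content(self) -> float:
        total = sum(self.lengths.values())
        gc = sum(_seq.gc_fraction(s) * len(s) for s in self.sequences.values())
        return gc / total if total else 0.0

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeRef":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def write_fai(self, path: str | Path, width: int = 60) -> None:
        """A samtools-style .fai index matching :meth:`to_fasta` output."""
        offset = 0
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                offset += len(name) + 2  # '>' + name + newline
                n = len(seq)
                fh.write(f"{name}\t{n}\t{offset}\t{width}\t{width + 1}\n")
                offset += n + -(-n // width)  # sequence bytes plus newlines


@dataclass
class TruthCircle:
    """A planted circle: the acceptance oracle for the whole pipeline."""

    circle_id: str
    fragments: list[tuple[str, int, int, str]]  # (chrom, start, end, strand), 0-based half-open
    contains_mssi_site: bool = False
    is_mito_like: bool = False

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e, _ in self.fragments)

    @property
    def form(self) -> str:
        chroms = {c for c, *_ in self.fragments}
        return "simple" if len(chroms) == 1 else "complex"


@dataclass
class SimRead:
    read_id: str
    sequence: str
    quality: str  # Sanger-scaled phred string
    source_circle_id: str | None  # None for linear / ghost reads
    n_passes: float
    rotation_offset: int

    @property
    def mean_quality(self) -> float:
        return float(np.mean([ord(c) - 33 for c in self.quality]))


@dataclass
class SimReadSet:
    """Simulated reads plus the alignments an ideal aligner would report."""

    reads: list[SimRead]
    paf_rows: list[tuple] = field(default_factory=list)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")

    def write_paf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for line in self.paf_lines():
                fh.write(line + "\n")

    def paf_lines(self) -> list[str]:
        return ["\t".join(str(x) for x in row) for row in self.paf_rows]


# ---------------------------------------------------------------------------
# genome and annotation


def generate_genome(
    n_chroms: int,
    chrom_length: int,
    gc_fraction: float,
    seed: int,
    include_mito: bool = False,
    mito_length: int = MITO_LENGTH,
) -> GenomeRef:
    """Random i.i.d. genome of ``n_chroms`` equal-length chromosomes.

    ``include_mito`` appends a mitochondria-like contig named ``chrM_sim``
    so a mito-like circle has a distinct origin for depletion tests.
    """
    if n_chroms < 2:
        raise ValueError(f"n_chroms must be >= 2, got {n_chroms}")
    if chrom_length < 50_000:
        raise ValueError(f"chrom_length must be >= 50000, got {chrom_length}")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError(f"gc_fraction must be in (0, 1), got {gc_fraction}")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    for i in range(n_chroms):
        sequences[f"chr{i + 1}"] = _seq.random_sequence(chrom_length, gc_fraction, rng)
    if include_mito:
        sequences[MITO_CHROM] = _seq.random_sequence(mito_length, 0.44, rng)
    return GenomeRef(sequences)


#: Feature densities are per Mb; length ranges in bp.
DEFAULT_FEATURE_CONFIG: dict[str, dict] = {
    "gene": {
        "density": 8.0,
        "length": (3_000, 12_000),
        "exons": (2, 6),
        "exon_fraction": 0.35,
        "utr_fraction": 0.4,
    },
    "CpG": {"density": 8.0, "length": (300, 1_500)},
    "SINE": {"density": 40.0, "length": (100, 400)},
    "LINE": {"density": 12.0, "length": (500, 3_000)},
    "LTR": {"density": 8.0, "length": (300, 1_000)},
}

_KNOWN_CLASSES = {"gene", "exon", "intron", "5UTR", "3UTR", "CpG", "SINE", "LINE", "LTR"}


def _gene_model(
    chrom: str, gs: int, ge: int, name: str, cfg: dict, rng: np.random.Generator
) -> list[tuple[str, int, int, str, str]]:
    """Partition a gene interval into exons and introns; carve UTRs out of
    the terminal exons.  Exons and introns tile the gene exactly."""
    glen = ge - gs
    lo, hi = cfg.get("exons", (2, 6))
    n_exons = int(rng.integers(lo, hi + 1))
    feats: list[tuple[str, int, int, str, str]] = [(chrom, gs, ge, "gene", name)]
    if n_exons == 1:
        feats.append((chrom, gs, ge, "exon", f"{name}.e1"))
        exon_spans = [(gs, ge)]
    else:
        exon_total = max(n_exons * 20, int(round(cfg.get("exon_fraction", 0.35) * glen)))
        exon_total = min(exon_total, glen - (n_exons - 1) * 20)
        intron_total = glen - exon_total
        ew = rng.dirichlet(np.ones(n_exons))
        iw = rng.dirichlet(np.ones(n_exons - 1))
        exon_lens = np.maximum(20, np.round(ew * exon_total).astype(int))
        intron_lens = np.maximum(20, np.round(iw * intron_total).astype(int))
        # rebalance rounding drift onto the largest exon
        exon_lens[int(np.argmax(exon_lens))] += glen - int(exon_lens.sum() + intron_lens.sum())
        pos = gs
        exon_spans = []
        for k in range(n_exons):
            e_end = pos + int(exon_lens[k])
            feats.append((chrom, pos, e_end, "exon", f"{name}.e{k + 1}"))
            exon_spans.append((pos, e_end))
            pos = e_end
            if k < n_exons - 1:
                i_end = pos + int(intron_lens[k])
                feats.append((chrom, pos, i_end, "intron", f"{name}.i{k + 1}"))
                pos = i_end
        assert pos == ge, "gene partition must tile the gene exactly"
    utr_frac = cfg.get("utr_fraction", 0.4)
    f_s, f_e = exon_spans[0]
    l_s, l_e = exon_spans[-1]
    u5 = max(1, int(round((f_e - f_s) * utr_frac)))
    u3 = max(1, int(round((l_e - l_s) * utr_frac)))
    if len(exon_spans) == 1:  # keep the two UTRs disjoint inside a single exon
        u5 = min(u5, (f_e - f_s) // 2)
        u3 = min(u3, (f_e - f_s) - u5)
    feats.append((chrom, f_s, f_s + u5, "5UTR", f"{name}.utr5"))
    feats.append((chrom, l_e - u3, l_e, "3UTR", f"{name}.utr3"))
    return feats


def plant_annotation(
    genome: GenomeRef,
    feature_config: dict | None = None,
    seed: int = 0,
) -> AnnotationTrack:
    """Plant a random annotation: genes with exon/intron/UTR substructure,
    CpG islands and repeat classes.  Repeats may overlap anything, as in
    real genomes; genes never overlap each other."""
    cfg = feature_config if feature_config is not None else DEFAULT_FEATURE_CONFIG
    unknown = set(cfg) - _KNOWN_CLASSES
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    features: list[tuple[str, int, int, str, str]] = []
    gene_idx = 0
    rep_idx: dict[str, int] = {}
    for chrom, clen in genome.lengths.items():
        if chrom == MITO_CHROM:
            continue
        gcfg = cfg.get("gene")
        if gcfg and gcfg.get("density", 0) > 0:
            n_genes = int(round(gcfg["density"] * clen / 1e6))
            lo, hi = gcfg["length"]
            if n_genes * lo > 0.8 * clen:
                raise ValueError(
                    f"gene density {gcfg['density']}/Mb with min length {lo} cannot fit "
                    f"chromosome {chrom} ({clen} bp)"
                )
            placed: list[tuple[int, int]] = []
            for _ in range(n_genes):
                glen = int(rng.integers(lo, hi + 1))
                for _attempt in range(200):
                    gs = int(rng.integers(0, clen - glen + 1))
                    ge = gs + glen
                    if all(ge <= s or gs >= e for s, e in placed):
                        placed.append((gs, ge))
                        gene_idx += 1
                        features.extend(
                            _gene_model(chrom, gs, ge, f"gene{gene_idx:04d}", gcfg, rng)
                        )
                        break
                else:
                    raise ValueError(f"cannot place gene of {glen} bp on {chrom}: capacity exceeded")
        for cls in ("CpG", "SINE", "LINE", "LTR"):
            ccfg = cfg.get(cls)
            if not ccfg or ccfg.get("density", 0) <= 0:
                continue
            n_feat = int(round(ccfg["density"] * clen / 1e6))
            lo, hi = ccfg["length"]
            if lo > clen:
                raise ValueError(f"{cls} minimum length {lo} exceeds chromosome {chrom}")
            for _ in range(n_feat):
                flen = int(rng.integers(lo, hi + 1))
                fs = int(rng.integers(0, clen - flen + 1))
                rep_idx[cls] = rep_idx.get(cls, 0) + 1
                features.append((chrom, fs, fs + flen, cls, f"{cls}_{rep_idx[cls]:04d}"))
    return AnnotationTrack(features)


# ---------------------------------------------------------------------------
# circles


def circle_sequence(circle: TruthCircle, genome: GenomeRef) -> str:
    """The circle's sequence: fragment reference sequences concatenated in
    order, reverse-complemented for minus-strand fragments."""
    parts = []
    for chrom, s, e, strand in circle.fragments:
        seq = genome.fetch(chrom, s, e)
        parts.append(_seq.revcomp(seq) if strand == "-" else seq)
    return "".join(parts)


def _overlaps_occupied(
    occupied: dict[str, list[tuple[int, int]]], chrom: str, start: int, end: int, pad: int
) -> bool:
    return any(start - pad < e and end + pad > s for s, e in occupied.get(chrom, ()))


def sample_circles(
    genome: GenomeRef,
    n_simple: int,
    n_complex: int,
    size_range: tuple[int, int] = (300, 8_000),
    mssi_fraction: float = 0.0,
    include_mito_like: bool = False,
    seed: int = 0,
    min_fragment: int = MIN_FRAGMENT,
    spacing: int = 20_000,
) -> list[TruthCircle]:
    """Plant circles on the genome, uniformly over nuclear positions.

    Complex circles use 2-4 fragments from >=2 chromosomes.  For
    ``mssi_fraction`` of the nuclear circles the MssI recognition sequence
    is written into the genome inside one fragment (mutating ``genome`` in
    place); ``contains_mssi_site`` is then set by scanning each circle's
    actual sequence, so chance occurrences are flagged too.  Fragments of
    distinct circles are kept >= ``spacing`` bp apart so that background
    reads cannot merge two circles' regions into one.
    """
    lo, hi = size_range
    if not (200 <= lo < hi <= 100_000):
        raise ValueError(f"size_range must lie within [200, 100000], got {size_range}")
    if lo < min_fragment:
        raise ValueError(f"size_range minimum {lo} is below minimum fragment length {min_fragment}")
    rng = np.random.default_rng(seed)
    nuclear = [c for c in genome.chrom_names if c != MITO_CHROM]
    if len(nuclear) < 2 and n_complex > 0:
        raise ValueError("complex circles need >= 2 nuclear chromosomes")
    lengths = genome.lengths
    weights = np.array([lengths[c] for c in nuclear], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {}
    circles: list[TruthCircle] = []

    def _place(chrom: str, flen: int) -> int | None:
        clen = lengths[chrom]
        if flen >= clen:
            return None
        for _ in range(1_000):
            s = int(rng.integers(0, clen - flen + 1))
            if not _overlaps_occupied(occupied, chrom, s, s + flen, spacing):
                return s
        return None

    for i in range(n_simple):
        for _ in range(100):
            total = int(rng.integers(lo, hi + 1))
            chrom = str(rng.choice(nuclear, p=weights))
            s = _place(chrom, total)
            if s is not None:
                occupied.setdefault(chrom, []).append((s, s + total))
                circles.append(TruthCircle(f"truth{i:03d}", [(chrom, s, s + total, "+")]))
                break
        else:
            raise RuntimeError("could not place simple circle; genome too crowded")

    for j in range(n_complex):
        for _ in range(100):
            total = int(rng.integers(lo, hi + 1))
            k = int(rng.integers(2, 5))
            if total < k * min_fragment:
                k = max(2, total // min_fragment)
            w = rng.dirichlet(np.ones(k))
            flens = np.maximum(min_fragment, np.round(w * total).astype(int))
            flens[int(np.argmax(flens))] += total - int(flens.sum())
            if flens.min() < min_fragment:
                continue
            chroms = [str(c) for c in rng.choice(nuclear, size=k, p=weights)]
            if len(set(chroms)) < 2:
                continue
            frags: list[tuple[str, int, int, str]] = []
            for fi, (chrom, flen) in enumerate(zip(chroms, flens)):
                s = _place(chrom, int(flen))
                if s is None:
                    break
                strand = "+" if fi == 0 else str(rng.choice(["+", "-"]))
                frags.append((chrom, s, s + int(flen), strand))
            if len(frags) == k:
                for chrom, s, e, _ in frags:
                    occupied.setdefault(chrom, []).append((s, e))
                circles.append(TruthCircle(f"truth{n_simple + j:03d}", frags))
                break
        else:
            raise RuntimeError("could not place complex circle; genome too crowded")

    # plant the restriction site into a subset of nuclear circles
    n_sites = int(round(mssi_fraction * len(circles)))
    if n_sites > 0:
        chosen = rng.choice(len(circles), size=n_sites, replace=False)
        m = len(MSSI_SITE)
        for ci in sorted(int(c) for c in chosen):
            frags = circles[ci].fragments
            flens = np.array([e - s for _, s, e, _ in frags], dtype=float)
            fi = int(rng.choice(len(frags), p=flens / flens.sum()))
            chrom, s, e, _ = frags[fi]
            pos = int(rng.integers(s, e - m + 1))
            seq = genome.sequences[chrom]
            genome.sequences[chrom] = seq[:pos] + MSSI_SITE + seq[pos + m :]

    if include_mito_like:
        if MITO_CHROM not in genome.sequences:
            raise ValueError(
                f"genome has no {MITO_CHROM} contig; generate it with include_mito=True"
            )
        mlen = lengths[MITO_CHROM]
        circles.append(
            TruthCircle("mito", [(MITO_CHROM, 0, mlen, "+")], is_mito_like=True)
        )

    # flag site carriers by scanning the actual circular sequence
    m = len(MSSI_SITE)
    for c in circles:
        seq = circle_sequence(c, genome)
        c.contains_mssi_site = bool(_seq.find_motif(seq + seq[: m - 1], MSSI_SITE))
    return circles


def apply_enzyme_model(
    circles: list[TruthCircle],
    mode: str,
    cas9_mito_efficiency: float = 0.86,
    seed: int = 0,
) -> list[TruthCircle]:
    """Which circles survive the mtDNA-depletion step.

    ``mssi``: the mito-like circle and every circle carrying the GTTTAAAC
    site are linearized and lost to exonuclease (deterministic).
    ``cas9``: only the mito-like circle is at risk, removed with
    probability ``cas9_mito_efficiency``; nuclear site-bearing circles are
    never touched.
    """
    if mode not in ("mssi", "cas9"):
        raise ValueError(f"mode must be 'mssi' or 'cas9', got {mode!r}")
    if not (0.0 <= cas9_mito_efficiency <= 1.0):
        raise ValueError("cas9_mito_efficiency must be in [0, 1]")
    if mode == "mssi":
        return [c for c in circles if not c.is_mito_like and not c.contains_mssi_site]
    rng = np.random.default_rng(seed)
    out = []
    for c in circles:
        if c.is_mito_like and rng.random() < cas9_mito_efficiency:
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# reads


def _draw_passes(spec, rng: np.random.Generator) -> float:
    kind, value = spec
    if kind == "fixed":
        if value < 0:
            raise ValueError("fixed pass count must be >= 0")
        return float(value)
    if kind == "geometric":
        # geometric on {1, 2, ...} with the requested mean
        if value <= 1:
            return 1.0
        return float(rng.geometric(1.0 / value))
    raise ValueError(f"unknown passes distribution {spec!r}")


def _phred_string(n: int, mean_quality: float, rng: np.random.Generator) -> tuple[str, float]:
    q = np.clip(np.round(rng.normal(mean_quality, 4.0, size=n)), 2, 41).astype(int)
    return "".join(chr(33 + v) for v in q), float(q.mean())


def _segment_blocks(circle: TruthCircle, rot: int, total: int):
    """Split a tandem copy of ``total`` bases starting at circle offset
    ``rot`` into maximal single-fragment segments with genome coordinates."""
    frags = circle.fragments
    bounds = np.cumsum([0] + [e - s for _, s, e, _ in frags])
    L = int(bounds[-1])
    segs = []  # (chrom, ref_start, ref_end, strand, seg_len)
    pos, remaining = rot % L, total
    while remaining > 0:
        fi = int(np.searchsorted(bounds, pos, side="right")) - 1
        frag_end = int(bounds[fi + 1])
        span = min(frag_end - pos, remaining)
        chrom, fs, fe, strand = frags[fi]
        o1 = pos - int(bounds[fi])
        o2 = o1 + span
        if strand == "+":
            segs.append((chrom, fs + o1, fs + o2, "+", span))
        else:
            segs.append((chrom, fe - o2, fe - o1, "-", span))
        pos = (pos + span) % L
        remaining -= span
    return segs


def simulate_reads(
    circles: list[TruthCircle],
    genome: GenomeRef,
    reads_per_circle: int,
    passes_distribution: tuple = ("geometric", 4.0),
    linear_read_count: int = 0,
    error_rates: tuple[float, float, float] = (0.01, 0.0025, 0.0025),
    seed: int = 0,
    *,
    linear_length_range: tuple[int, int] = (500, 15_000),
    ghost_read_count: int = 0,
    mean_quality: float = 20.0,
    both_strands: bool = True,
    max_read_length: int = 90_000,
) -> SimReadSet:
    """Simulate rolling-circle concatemer reads plus background.

    Each circular read starts at a uniformly random rotation of its circle
    and copies the circle tandemly for its drawn pass count (fractional
    passes truncate the final copy).  The truth PAF records every aligned
    block exactly as an ideal aligner would report it.  Linear reads are
    contiguous genome windows; ghost reads are unalignable random sequence
    present in the FASTQ only.
    """
    sub, ins, dele = error_rates
    for name, rate in zip(("substitution", "insertion", "deletion"), error_rates):
        if not (0.0 <= rate < 0.2):
            raise ValueError(f"{name} rate must be in [0, 0.2), got {rate}")
    if reads_per_circle > 0 and not circles:
        raise ValueError("reads_per_circle > 0 but the circle list is empty")
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    reads: list[SimRead] = []
    paf_rows: list[tuple] = []

    def _emit(read_id, pieces, blocks, source, n_passes, rot):
        # pieces: list of mutated index arrays, one per block, in read order
        # blocks: list of (chrom, ref_start, ref_end, strand, n_match)
        idx = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
        spans = []
        off = 0
        for p in pieces:
            spans.append((off, off + len(p)))
            off += len(p)
        flip = both_strands and bool(rng.random() < 0.5)
        qlen = len(idx)
        if flip:
            idx = _seq.revcomp_idx(idx)
            spans = [(qlen - e, qlen - s) for s, e in spans][::-1]
            blocks = [(c, rs, re, "-" if st == "+" else "+", nm) for c, rs, re, st, nm in blocks][::-1]
        seq = _seq.decode(idx)
        qual, mean_q = _phred_string(qlen, mean_quality, rng)
        reads.append(SimRead(read_id, seq, qual, source, n_passes, rot))
        for (qs, qe), (chrom, rs, re, strand, nm) in zip(spans, blocks):
            if qe <= qs:
                continue
            paf_rows.append(
                (
                    read_id, qlen, qs, qe, strand, chrom, lengths[chrom], rs, re,
                    nm, max(qe - qs, re - rs), 60, f"rq:f:{mean_q:.1f}",
                )
            )

    for circle in circles:
        cseq_idx = _seq.encode(circle_sequence(circle, genome))
        L = len(cseq_idx)
        for j in range(reads_per_circle):
            n_passes = _draw_passes(passes_distribution, rng)
            n_passes = min(n_passes, max_read_length / L)
            rot = int(rng.integers(0, L))
            total = int(round(n_passes * L))
            if total < 1:
                total = 1
            segs = _segment_blocks(circle, rot, total)
            pieces, blocks = [], []
            pos = rot
            for chrom, rs, re, strand, span in segs:
                o1 = pos % L
                template = cseq_idx[o1 : o1 + span]
                piece, nm = _seq.mutate_idx(template, sub, ins, dele, rng)
                pieces.append(piece)
                blocks.append((chrom, rs, re, strand, nm))
                pos += span
            _emit(f"{circle.circle_id}_r{j:04d}", pieces, blocks, circle.circle_id, n_passes, rot)

    nuclear = [c for c in genome.chrom_names if c != MITO_CHROM]
    w = np.array([lengths[c] for c in nuclear], dtype=float)
    w /= w.sum()
    llo, lhi = linear_length_range
    for i in range(linear_read_count):
        chrom = str(rng.choice(nuclear, p=w))
        rl = int(rng.integers(llo, min(lhi, lengths[chrom] - 1) + 1))
        s = int(rng.integers(0, lengths[chrom] - rl + 1))
        template = _seq.encode(genome.fetch(chrom, s, s + rl))
        piece, nm = _seq.mutate_idx(template, sub, ins, dele, rng)
        _emit(f"linear{i:05d}", [piece], [(chrom, s, s + rl, "+", nm)], None, 0.0, 0)

    for i in range(ghost_read_count):
        n = int(rng.integers(300, 2_001))
        idx = rng.integers(0, 4, size=n).astype(np.uint8)
        seq = _seq.decode(idx)
        qual, _ = _phred_string(n, mean_quality, rng)
        reads.append(SimRead(f"ghost{i:04d}", seq, qual, None, 0.0, 0))

    return SimReadSet(reads, paf_rows)


def write_circle_manifest(circles: list[TruthCircle], path: str | Path) -> None:
    """Truth tables: a per-fragment BED-like table plus a circle manifest."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("circle_id\tform\ttotal_length\tcontains_mssi_site\tis_mito_like\tfragments\n")
        for c in circles:
            frag_str = ",".join(f"{ch}:{s}-{e}({st})" for ch, s, e, st in c.fragments)
            fh.write(
                f"{c.circle_id}\t{c.form}\t{c.total_length}\t"
                f"{int(c.contains_mssi_site)}\t{int(c.is_mito_like)}\t{frag_str}\n"
            )
    bed = path.with_suffix(".fragments.bed")
    with open(bed, "w") as fh:
        for c in circles:
            for fi, (ch, s, e, st) in enumerate(c.fragments):
                fh.write(f"{ch}\t{s}\t{e}\t{c.circle_id}.{fi}\t0\t{st}\n")
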