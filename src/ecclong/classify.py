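"""Per-read alignment ingestion, ghost filtering and read-type classification.

Long reads from rolling-circle-amplified circular templates leave two
alignment signatures: *breakpoint* reads join reference-discontiguous
loci at a junction, and *CTC* (circular template concatenation) reads
contain two or more tandem copies of the circle — the defining evidence
of circularity.  Reads that align contiguously are *normal*; reads with
no usable alignment or failing the quality floors are *ghost*.

CTC reads are trimmed to a single complete pass of the circle before
region building, so one concatemer contributes each locus once.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

logging.getLogger(__name__).addHandler(logging.NullHandler())
logger = logging.getLogger(__name__)

LABELS = ("ghost", "normal", "breakpoint", "ctc")

__all__ = [
    "AlignmentBlock",
    "ReadProfile",
    "EmptyInputError",
    "load_alignments",
    "filter_reads",
    "classify_read",
    "trim_ctc",
    "LABELS",
]


class EmptyInputError(ValueError):
    """No usable alignment rows in the input."""


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned block of one read, 0-based half-open on both axes."""

    read_id: str
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    read_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end <= self.read_length):
            raise ValueError(
                f"bad read span {self.read_start}-{self.read_end} for {self.read_id} "
                f"(length {self.read_length})"
            )
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError(f"bad reference span {self.ref_start}-{self.ref_end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class ReadProfile:
    """Ordered aligned blocks of one read on the reference."""

    read_id: str
    read_length: int
    blocks: list[AlignmentBlock]
    mean_quality: float | None = None
    ctc_trimmed: bool = False
    implied_length: int | None = None

    @property
    def aligned_fraction(self) -> float:
        return sum(b.read_span for b in self.blocks) / self.read_length

    def sorted_blocks(self) -> list[AlignmentBlock]:
        return sorted(self.blocks, key=lambda b: b.read_start)


# ---------------------------------------------------------------------------
# PAF ingestion


def _truncate_block(b: AlignmentBlock, new_start: int, new_end: int) -> AlignmentBlock:
    """Trim a block to a read sub-span, shifting the reference span by the
    same amounts (block-level colinearity assumption)."""
    left = new_start - b.read_start
    right = b.read_end - new_end
    if b.strand == "+":
        rs, re = b.ref_start + left, b.ref_end - right
    else:
        rs, re = b.ref_start + right, b.ref_end - left
    re = max(re, rs + 1)  # degenerate spans from heavy trimming keep 1 bp
    return replace(b, read_start=new_start, read_end=new_end, ref_start=rs, ref_end=re)


def _resolve_overlaps(blocks: list[AlignmentBlock], min_block: int = 30) -> list[AlignmentBlock]:
    """Make blocks non-overlapping in read coordinates.

    Priority: higher mapq first, ties to the longer block.  Lower-priority
    blocks are truncated to their largest uncovered read sub-span, or
    dropped if less than ``min_block`` bp survives.
    """
    order = sorted(blocks, key=lambda b: (-b.mapq, -b.read_span, b.read_start, b.ref_start))
    kept: list[AlignmentBlock] = []
    occupied: list[tuple[int, int]] = []
    for b in order:
        gaps = [(b.read_start, b.read_end)]
        for s, e in occupied:
            gaps = [
                piece
                for gs, ge in gaps
                for piece in ((gs, min(ge, s)), (max(gs, e), ge))
                if piece[0] < piece[1]
            ]
        if not gaps:
            continue
        gs, ge = max(gaps, key=lambda g: (g[1] - g[0], -g[0]))
        if ge - gs < min(min_block, b.read_span):
            continue
        nb = b if (gs, ge) == (b.read_start, b.read_end) else _truncate_block(b, gs, ge)
        kept.append(nb)
        occupied.append((gs, ge))
        occupied.sort()
    return sorted(kept, key=lambda b: b.read_start)


def load_alignments(
    source: str | Path | Iterable[str],
    min_mapq: int = 1,
) -> list[ReadProfile]:
    """Parse PAF rows into one :class:`ReadProfile` per read.

    Rows for one read may be interleaved.  Malformed rows are skipped with
    a warning; zero usable rows raise :class:`EmptyInputError`.  Blocks
    overlapping in read coordinates are resolved by keeping the
    higher-mapq block and truncating the other (ties: keep the longer).
    An ``rq:f:`` tag, when present, supplies the read's mean base quality.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return load_alignments(list(fh), min_mapq=min_mapq)
    per_read: dict[str, list[AlignmentBlock]] = {}
    read_qual: dict[str, float] = {}
    order: list[str] = []
    n_malformed = 0
    for line in source:
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        try:
            if len(cols) < 12:
                raise ValueError("fewer than 12 columns")
            qname, qlen, qs, qe = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
            strand, tname = cols[4], cols[5]
            ts, te, mapq = int(cols[7]), int(cols[8]), int(cols[11])
            block = AlignmentBlock(qname, qs, qe, tname, ts, te, strand, mapq, qlen)
        except (ValueError, IndexError):
            n_malformed += 1
            continue
        for tag in cols[12:]:
            if tag.startswith("rq:f:"):
                read_qual[qname] = float(tag[5:])
        if block.mapq < min_mapq:
            continue
        if qname not in per_read:
            per_read[qname] = []
            order.append(qname)
        per_read[qname].append(block)
    if n_malformed:
        logger.warning("skipped %d malformed PAF rows", n_malformed)
    if not per_read:
        raise EmptyInputError("no usable alignment rows in PAF input")
    profiles = []
    for qname in order:
        blocks = _resolve_overlaps(per_read[qname])
        if not blocks:
            continue
        profiles.append(
            ReadProfile(qname, blocks[0].read_length, blocks, read_qual.get(qname))
        )
    return profiles


# ---------------------------------------------------------------------------
# ghost filtering


def filter_reads(
    profiles: list[ReadProfile],
    min_mean_q: float = 10.0,
    min_aligned_fraction: float = 0.3,
    min_read_length: int = 200,
) -> tuple[list[ReadProfile], int]:
    """Remove ghost reads: too short, too poorly aligned, or too low quality.

    Profiles without a known mean quality pass the quality check (aligner
    PAFs carry no base qualities).  Returns (kept, ghost_count).
    """
    kept, ghosts = [], 0
    for p in profiles:
        ok = (
            p.read_length >= min_read_length
            and p.aligned_fraction >= min_aligned_fraction
            and (p.mean_quality is None or p.mean_quality >= min_mean_q)
        )
        if ok:
            kept.append(p)
        else:
            ghosts += 1
    return kept, ghosts


# ---------------------------------------------------------------------------
# classification


def _same_locus(a: AlignmentBlock, b: AlignmentBlock, tol: int, min_reciprocal: float) -> bool:
    """Two blocks cover the same reference interval in the same orientation:
    reciprocal overlap >= ``min_reciprocal`` and both boundaries within
    ``tol`` bp — tolerant to alignment jitter while rejecting paralogy."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    if ov <= 0:
        return False
    if ov < min_reciprocal * max(a.ref_span, b.ref_span):
        return False
    return abs(a.ref_start - b.ref_start) <= tol and abs(a.ref_end - b.ref_end) <= tol


def colinear(a: AlignmentBlock, b: AlignmentBlock, tol: int = 50) -> bool:
    """Consecutive read blocks continue one contiguous reference locus."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    read_gap = b.read_start - a.read_end
    if a.strand == "+":
        ref_gap = b.ref_start - a.ref_end
    else:
        ref_gap = a.ref_start - b.ref_end
    return abs(ref_gap - read_gap) <= tol and ref_gap >= -tol


def _duplicated_footprint_fraction(blocks: list[AlignmentBlock]) -> float:
    """Fraction of the read's reference footprint traversed >= 2 times in
    the same orientation."""
    from collections import defaultdict

    events: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for b in blocks:
        events[(b.chrom, b.strand)].append((b.ref_start, 1))
        events[(b.chrom, b.strand)].append((b.ref_end, -1))
    footprint = dup = 0
    for ev in events.values():
        ev.sort()
        depth = 0
        prev = None
        for pos, delta in ev:
            if prev is not None and pos > prev:
                if depth >= 1:
                    footprint += pos - prev
                if depth >= 2:
                    dup += pos - prev
            depth += delta
            prev = pos
    return dup / footprint if footprint else 0.0


def classify_read(
    profile: ReadProfile,
    same_locus_tolerance: int = 50,
    min_reciprocal_overlap: float = 0.8,
    min_duplicated_fraction: float = 0.8,
    colinear_tolerance: int = 50,
) -> str:
    """Label a read ``ctc``, ``breakpoint`` or ``normal``.

    ``ctc``: two blocks at different read positions cover the same
    reference locus in the same orientation, or >= 80% of the read's
    reference footprint is multiply traversed (which catches concatemers
    whose rotation splits every copy).  Circularity evidence dominates: a
    read with both signatures is ``ctc``.

    ``breakpoint``: adjacent read blocks are reference-discontiguous
    (different chromosome, strand, or a non-colinear jump).

    ``normal``: a single block, or colinear blocks consistent with one
    contiguous locus.
    """
    blocks = profile.sorted_blocks()
    if not blocks:
        raise ValueError(f"profile {profile.read_id} has no blocks")
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if _same_locus(blocks[i], blocks[j], same_locus_tolerance, min_reciprocal_overlap):
                return "ctc"
    if len(blocks) > 1 and _duplicated_footprint_fraction(blocks) >= min_duplicated_fraction:
        return "ctc"
    for a, b in zip(blocks, blocks[1:]):
        if not colinear(a, b, colinear_tolerance):
            return "breakpoint"
    return "normal"


# ---------------------------------------------------------------------------
# CTC trimming


def _clip_to_ref(b: AlignmentBlock, rs: int, re: int) -> AlignmentBlock:
    """Clip a block to a reference sub-span, shifting read coordinates by
    the same amounts."""
    left, right = rs - b.ref_start, b.ref_end - re
    if b.strand == "+":
        qs, qe = b.read_start + left, b.read_end - right
    else:
        qs, qe = b.read_start + right, b.read_end - left
    qs, qe = max(qs, b.read_start), min(qe, b.read_end)
    if qe <= qs:
        qe = qs + 1
    return replace(b, read_start=qs, read_end=qe, ref_start=rs, ref_end=re)


def trim_ctc(profile: ReadProfile, tolerance: int = 50) -> ReadProfile:
    """Trim a CTC read to exactly one complete pass of its circle.

    Walk the blocks in read order, keeping the novel reference portion of
    each; stop at the first block that is (within ``tolerance``) entirely
    a repetition of already-seen loci.  The retained blocks cover each
    constituent locus once; the implied circle length (sum of retained
    reference spans) is recorded.  Idempotent: trimming a trimmed profile
    is a no-op.  Raises if the profile was never a CTC read.
    """
    if profile.ctc_trimmed:
        return profile
    if classify_read(profile, same_locus_tolerance=tolerance) != "ctc":
        raise ValueError(f"trim_ctc requires a ctc-labeled profile, got {profile.read_id}")
    seen: dict[tuple[str, str], list[tuple[int, int]]] = {}
    retained: list[AlignmentBlock] = []
    for b in profile.sorted_blocks():
        key = (b.chrom, b.strand)
        ivs = seen.setdefault(key, [])
        gaps = [(b.ref_start, b.ref_end)]
        for s, e in ivs:
            gaps = [
                piece
                for gs, ge in gaps
                for piece in ((gs, min(ge, s)), (max(gs, e), ge))
                if piece[0] < piece[1]
            ]
        novel_total = sum(ge - gs for gs, ge in gaps)
        repeated = b.ref_span - novel_total
        if repeated > 0 and novel_total <= tolerance:
            # (near-)full repetition of an already-seen locus: one pass done;
            # absorb the sub-tolerance novel remainder so the retained pass
            # covers the whole circle, then stop
            if gaps:
                tail = max(gaps, key=lambda g: g[1] - g[0])
                retained.append(_clip_to_ref(b, *tail))
            break
        novel = max(gaps, key=lambda g: g[1] - g[0])
        nb = b if novel == (b.ref_start, b.ref_end) else _clip_to_ref(b, *novel)
        retained.append(nb)
        ivs.append(novel)
        ivs.sort()
    implied = sum(b.ref_span for b in retained)
    return ReadProfile(
        profile.read_id,
        profile.read_length,
        retained,
        profile.mean_quality,
        ctc_trimmed=True,
        implied_length=implied,
    )
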