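"""Sample-level eccDNA statistics.

Size distributions and the below-3-kb enrichment, per-million read
normalization, chromosomal origin densities (count per Mb of
chromosome), the MssI/PmeI recognition-site census, binned coverage
tracks with 1x-genome (RPGC) normalization, replicate-summed gene depth
contrasts, and simple/complex form proportions.  Every statistic is a
pure function of its inputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _seq
from .classify import AlignmentBlock

MSSI_MOTIF = "GTTTAAAC"
SIZE_THRESHOLD = 3_000

__all__ = [
    "size_distribution",
    "normalize_per_million",
    "chrom_distribution",
    "scan_recognition_sites",
    "CoverageTrack",
    "coverage_track",
    "gene_depth_contrast",
    "form_proportions",
]


def _groups_of(calls, group_labels):
    if group_labels is None:
        return ["all"] * len(calls)
    if isinstance(group_labels, dict):
        return [group_labels[getattr(c, "ecc_id", getattr(c, "circle_id", None))] for c in calls]
    if len(group_labels) != len(calls):
        raise ValueError("group_labels must parallel calls")
    return list(group_labels)


def size_distribution(calls, group_labels=None, threshold: int = SIZE_THRESHOLD) -> pd.DataFrame:
    """Per-group call-length summary with the below-threshold fraction.

    Returns one row per group: n_calls, length quantiles (min, q25,
    median, q75, max) and ``fraction_below`` = count(length < threshold)/n.
    Empty groups are reported with n=0 and NaN statistics.
    """
    groups = _groups_of(calls, group_labels)
    lengths = pd.Series([c.total_length for c in calls], dtype=float)
    rows = []
    for g in sorted(set(groups)):
        vals = lengths[[gl == g for gl in groups]]
        if len(vals) == 0:
            rows.append({"group": g, "n_calls": 0, "min": np.nan, "q25": np.nan,
                         "median": np.nan, "q75": np.nan, "max": np.nan,
                         "fraction_below": np.nan})
            continue
        q = vals.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append(
            {
                "group": g,
                "n_calls": len(vals),
                "min": q.iloc[0],
                "q25": q.iloc[1],
                "median": q.iloc[2],
                "q75": q.iloc[3],
                "max": q.iloc[4],
                "fraction_below": float((vals < threshold).mean()),
            }
        )
    return pd.DataFrame(rows)


def normalize_per_million(n_ecc: int, n_reads: int) -> float:
    """eccDNA count per million sequenced reads."""
    if n_reads <= 0:
        raise ZeroDivisionError("n_reads must be > 0 for per-million normalization")
    return n_ecc * 1_000_000 / n_reads


def chrom_distribution(calls, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Chromosomal origins, normalized by chromosome length.

    Each call is assigned to the chromosome of its canonical (first)
    fragment (``raw_count``); complex calls additionally contribute one
    count per extra constituent chromosome, flagged separately in
    ``complex_extra`` so neither reading of multi-chromosome circles is
    lost.  ``density_per_mb`` = raw_count / (chromosome length in Mb).
    """
    raw = {c: 0 for c in chrom_lengths}
    extra = {c: 0 for c in chrom_lengths}
    for call in calls:
        chroms = [f[0] for f in call.fragments]
        for ch in set(chroms):
            if ch not in chrom_lengths:
                raise ValueError(f"call fragment on unknown chromosome {ch!r}")
        canonical = chroms[0]
        raw[canonical] += 1
        for ch in sorted(set(chroms) - {canonical}):
            extra[ch] += 1
    rows = []
    for ch, clen in chrom_lengths.items():
        rows.append(
            {
                "chrom": ch,
                "length": clen,
                "raw_count": raw[ch],
                "complex_extra": extra[ch],
                "density_per_mb": raw[ch] / (clen / 1e6),
            }
        )
    return pd.DataFrame(rows)


def scan_recognition_sites(
    sequence: str,
    motif: str = MSSI_MOTIF,
    circular: bool = False,
    both_strands: bool = False,
) -> list[int]:
    """All (possibly overlapping) occurrences of ``motif``; positions on
    the forward strand, 0-based.

    ``circular`` also finds matches spanning the origin by scanning the
    sequence extended with its first len(motif)-1 bases.  ``both_strands``
    unions forward hits with reverse-complement hits (reported at their
    forward-strand start); for a palindromic motif such as GTTTAAAC the
    two modes coincide.  'N' never matches.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    _seq.validate_alphabet(sequence)
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A,C,G,T}")
    seq = sequence.upper()
    m = len(motif)
    subject = seq + (seq[: m - 1] if circular and len(seq) >= 1 else "")
    hits = set(_seq.find_motif(subject, motif))
    if both_strands:
        rc = _seq.revcomp(motif)
        hits |= set(_seq.find_motif(subject, rc))
    n = len(seq)
    return sorted({h % n if circular else h for h in hits if h < n or circular})


@dataclass
class CoverageTrack:
    """Binned per-chromosome depth; bins tile each chromosome."""

    bin_size: int
    normalization: str
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]

    def genome_mean(self) -> float:
        total = 0.0
        nbases = 0
        for chrom, vals in self.values.items():
            clen = self.chrom_lengths[chrom]
            widths = np.full(len(vals), self.bin_size, dtype=float)
            if clen % self.bin_size:
                widths[-1] = clen % self.bin_size
            total += float((vals * widths).sum())
            nbases += clen
        return total / nbases

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean depth over [start, end), weighting partial bins by overlap."""
        if chrom not in self.values:
            raise ValueError(f"unknown chromosome {chrom!r}")
        vals = self.values[chrom]
        b0, b1 = start // self.bin_size, (end - 1) // self.bin_size
        total = 0.0
        for b in range(b0, b1 + 1):
            bs, be = b * self.bin_size, min((b + 1) * self.bin_size, self.chrom_lengths[chrom])
            ov = min(end, be) - max(start, bs)
            total += vals[b] * ov
        return total / (end - start)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.values:
                vals = self.values[chrom]
                clen = self.chrom_lengths[chrom]
                for b, v in enumerate(vals):
                    if v == 0:
                        continue
                    s = b * self.bin_size
                    fh.write(f"{chrom}\t{s}\t{min(s + self.bin_size, clen)}\t{v:.6g}\n")


def coverage_track(
    blocks: list[AlignmentBlock],
    chrom_lengths: dict[str, int],
    bin_size: int = 10,
    normalization: str = "rpgc",
) -> CoverageTrack:
    """Binned depth from aligned blocks.

    Per-bin depth = aligned bases in the bin / bin width.  ``rpgc``
    rescales the whole track so the genome-wide mean depth equals 1
    (1x genomic coverage); ``raw`` leaves fold-coverage as is.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if normalization not in ("rpgc", "raw"):
        raise ValueError(f"normalization must be 'rpgc' or 'raw', got {normalization!r}")
    base = {}
    for chrom, clen in chrom_lengths.items():
        nbins = (clen + bin_size - 1) // bin_size
        base[chrom] = np.zeros(nbins, dtype=float)
    total_aligned = 0
    for b in blocks:
        if b.chrom not in base:
            raise ValueError(f"block on unknown chromosome {b.chrom!r}")
        arr = base[b.chrom]
        clen = chrom_lengths[b.chrom]
        s, e = b.ref_start, min(b.ref_end, clen)
        total_aligned += e - s
        b0, b1 = s // bin_size, (e - 1) // bin_size
        if b0 == b1:
            arr[b0] += e - s
        else:
            arr[b0] += (b0 + 1) * bin_size - s
            arr[b1] += e - b1 * bin_size
            if b1 > b0 + 1:
                arr[b0 + 1 : b1] += bin_size
    for chrom, arr in base.items():
        clen = chrom_lengths[chrom]
        widths = np.full(len(arr), float(bin_size))
        if clen % bin_size:
            widths[-1] = clen % bin_size
        arr /= widths
    track = CoverageTrack(bin_size, normalization, base, dict(chrom_lengths))
    if normalization == "rpgc":
        genome_size = sum(chrom_lengths.values())
        if total_aligned == 0:
            raise ValueError("cannot RPGC-normalize an empty coverage track")
        scale = genome_size / total_aligned
        for arr in base.values():
            arr *= scale
    return track


def gene_depth_contrast(
    replicates: dict[str, list[list[AlignmentBlock]]],
    gene_intervals: list[tuple[str, int, int, str]],
    chrom_lengths: dict[str, int],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Replicate-summed per-gene read depth, contrasted between groups.

    ``replicates`` maps group -> list of per-replicate block lists.  For
    each gene the mean fold-coverage over the gene interval is computed
    per replicate and summed across replicates within the group.  With
    exactly two groups a ratio column (group_a + pc) / (group_b + pc) is
    added; the pseudocount keeps zero-coverage genes finite.
    """
    for chrom, *_ in gene_intervals:
        if chrom not in chrom_lengths:
            raise ValueError(f"gene on unknown chromosome {chrom!r}")
    groups = list(replicates)  # ratio direction follows the given group order
    sums: dict[str, np.ndarray] = {}
    for g in groups:
        acc = np.zeros(len(gene_intervals))
        for rep_blocks in replicates[g]:
            cov: dict[str, np.ndarray] = {}
            for b in rep_blocks:
                arr = cov.setdefault(b.chrom, np.zeros(chrom_lengths[b.chrom], dtype=np.int32))
                arr[b.ref_start : min(b.ref_end, len(arr))] += 1
            for i, (chrom, s, e, _name) in enumerate(gene_intervals):
                if chrom in cov:
                    acc[i] += float(cov[chrom][s:e].mean())
        sums[g] = acc
    out = pd.DataFrame(
        {
            "gene": [g[3] for g in gene_intervals],
            "chrom": [g[0] for g in gene_intervals],
            "start": [g[1] for g in gene_intervals],
            "end": [g[2] for g in gene_intervals],
        }
    )
    for g in groups:
        out[f"depth_sum_{g}"] = sums[g]
    if len(groups) == 2:
        a, b = groups
        out["ratio"] = (sums[a] + pseudocount) / (sums[b] + pseudocount)
    return out


def form_proportions(calls, group_labels=None) -> pd.DataFrame:
    """Per-group simple/complex fractions (summing to 1)."""
    groups = _groups_of(calls, group_labels)
    rows = []
    for g in sorted(set(groups)):
        sub = [c for c, gl in zip(calls, groups) if gl == g]
        n = len(sub)
        n_simple = sum(1 for c in sub if c.form == "simple")
        rows.append(
            {
                "group": g,
                "n_calls": n,
                "simple_fraction": n_simple / n if n else float("nan"),
                "complex_fraction": (n - n_simple) / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
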