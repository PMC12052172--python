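"""Genomic-feature annotation of eccDNA calls.

An :class:`AnnotationTrack` holds labeled genomic intervals (genes with
exon/intron/UTR substructure, CpG islands, repeat classes).  Each call is
intersected with every feature class to yield a per-call composition
(feature counts and covered bases); per-sample aggregates include the
intron:exon count ratio, the standard contrast in eccDNA composition
work.  Strand is ignored: composition is positional.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

FEATURE_CLASSES = (
    "gene", "exon", "intron", "5UTR", "3UTR", "CpG", "SINE", "LINE", "LTR", "other_repeat",
)

__all__ = [
    "FEATURE_CLASSES",
    "AnnotationTrack",
    "CompositionSummary",
    "annotate_call",
    "aggregate_composition",
    "CompositionAggregate",
]


class AnnotationTrack:
    """Labeled genomic intervals with an interval index for overlap queries.

    Features are (chrom, start, end, feature_class, name) with 0-based
    half-open coordinates and classes from the closed vocabulary
    :data:`FEATURE_CLASSES`.
    """

    def __init__(self, features: list[tuple[str, int, int, str, str]]):
        for chrom, start, end, cls, name in features:
            if not (0 <= start < end):
                raise ValueError(f"invalid interval {chrom}:{start}-{end} ({name})")
            if cls not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class {cls!r} ({name})")
        self.features = list(features)
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.features, columns=["chrom", "start", "end", "feature_class", "name"]
        )

    def _index(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
            for i, (chrom, start, end, cls, name) in enumerate(self.features):
                trees[chrom].addi(start, end, i)
            self._trees = dict(trees)
        return self._trees

    def query(self, chrom: str, start: int, end: int):
        """Features overlapping [start, end) on chrom, as feature tuples."""
        trees = self._index()
        if chrom not in trees:
            return []
        return [self.features[iv.data] for iv in sorted(trees[chrom].overlap(start, end))]

    # --- standard formats -------------------------------------------------

    def to_bed_dir(self, outdir: str | Path) -> dict[str, Path]:
        """One BED6 file per feature class."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        by_class: dict[str, list] = defaultdict(list)
        for feat in self.features:
            by_class[feat[3]].append(feat)
        paths = {}
        for cls, feats in by_class.items():
            p = outdir / f"{cls}.bed"
            with open(p, "w") as fh:
                for chrom, start, end, _, name in sorted(feats):
                    fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t+\n")
            paths[cls] = p
        return paths

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, start, end, cls, name in sorted(self.features):
                fh.write(
                    f"{chrom}\tecclong\t{cls}\t{start + 1}\t{end}\t.\t+\t.\tID={name}\n"
                )

    @classmethod
    def from_bed_files(cls, files: dict[str, str | Path]) -> "AnnotationTrack":
        """Build from {feature_class: bed_path}."""
        feats = []
        for fcls, path in files.items():
            with open(path) as fh:
                for i, line in enumerate(fh):
                    if not line.strip() or line.startswith(("#", "track")):
                        continue
                    cols = line.rstrip("\n").split("\t")
                    name = cols[3] if len(cols) > 3 else f"{fcls}_{i}"
                    feats.append((cols[0], int(cols[1]), int(cols[2]), fcls, name))
        return cls(feats)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationTrack":
        feats = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9 or cols[2] not in FEATURE_CLASSES:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                feats.append(
                    (cols[0], int(cols[3]) - 1, int(cols[4]), cols[2], attrs.get("ID", "."))
                )
        return cls(feats)


@dataclass
class CompositionSummary:
    """Feature content of one call: per-class feature counts and covered bases.

    A feature split across fragments of one call is counted once; its
    covered bases are summed over the intersections.
    """

    ecc_id: str
    total_length: int
    counts: dict[str, int] = field(default_factory=dict)
    bases: dict[str, int] = field(default_factory=dict)
    group: str | None = None

    def count(self, cls: str) -> int:
        return self.counts.get(cls, 0)

    def overlap_bases(self, cls: str) -> int:
        return self.bases.get(cls, 0)


def annotate_call(call, track: AnnotationTrack) -> CompositionSummary:
    """Intersect one eccDNA call with every feature class.

    ``call`` needs ``fragments`` (chrom, start, end, strand tuples), an id
    and a total length — both reconstructed calls and truth circles fit.
    """
    ecc_id = getattr(call, "ecc_id", None) or getattr(call, "circle_id", "call")
    seen: dict[tuple, int] = {}
    bases: dict[str, int] = defaultdict(int)
    counts: dict[str, int] = defaultdict(int)
    for chrom, fs, fe, _strand in call.fragments:
        for feat in track.query(chrom, fs, fe):
            fchrom, s, e, fcls, name = feat
            ov = min(fe, e) - max(fs, s)
            if ov <= 0:
                continue
            key = (fchrom, s, e, fcls, name)
            if key not in seen:
                seen[key] = 1
                counts[fcls] += 1
            bases[fcls] += ov
    total = getattr(call, "total_length")
    for cls, b in bases.items():
        bases[cls] = min(b, total)  # guard: fragment self-overlap cannot exceed call length
    return CompositionSummary(ecc_id, total, dict(counts), dict(bases))


@dataclass
class CompositionAggregate:
    table: pd.DataFrame  # one row per (group, feature_class)
    intron_exon_ratio: dict[str, float]


def aggregate_composition(
    summaries: list[CompositionSummary],
    group_labels: list[str] | None = None,
) -> CompositionAggregate:
    """Per-group composition totals and per-call means.

    Each summary carries a group label, either on the object or supplied
    in ``group_labels`` (parallel to ``summaries``).  Also reports the
    intron:exon feature-count ratio per group.
    """
    if group_labels is not None:
        if len(group_labels) != len(summaries):
            raise ValueError("group_labels must parallel summaries")
        for s, g in zip(summaries, group_labels):
            s.group = g
    for s in summaries:
        if s.group is None:
            raise ValueError(f"summary {s.ecc_id} has no group label")
    groups = sorted({s.group for s in summaries})
    rows = []
    ratios = {}
    for g in groups:
        subset = [s for s in summaries if s.group == g]
        n = len(subset)
        for cls in FEATURE_CLASSES:
            tc = sum(s.count(cls) for s in subset)
            tb = sum(s.overlap_bases(cls) for s in subset)
            rows.append(
                {
                    "group": g,
                    "feature_class": cls,
                    "n_calls": n,
                    "total_count": tc,
                    "total_bases": tb,
                    "mean_count_per_call": tc / n,
                    "mean_bases_per_call": tb / n,
                }
            )
        exon = sum(s.count("exon") for s in subset)
        intron = sum(s.count("intron") for s in subset)
        ratios[g] = intron / exon if exon else float("inf") if intron else float("nan")
    return CompositionAggregate(pd.DataFrame(rows), ratios)
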