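"""End-to-end orchestration: simulate -> classify -> call -> annotate -> characterize.

A run writes every stage output under one run directory together with
the effective configuration, a summary report and a checksum manifest,
so two runs with the same seed and configuration are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate as annotate_mod
from . import classify as classify_mod
from . import simulate as simulate_mod
from . import stats as stats_mod
from .calling import call_all
from .classify import trim_ctc

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "compare_groups"]


@dataclass
class RunConfig:
    """Every stage parameter in one place; unknown keys are rejected."""

    # run
    seed: int = 42
    outdir: str = "ecclong_run"
    group: str = "sample"
    # real-data inputs (when set, simulation is skipped)
    paf: str | None = None
    fasta: str | None = None
    annotation_gff: str | None = None
    # simulation
    n_chroms: int = 5
    chrom_length: int = 400_000
    gc_fraction: float = 0.41
    n_simple: int = 20
    n_complex: int = 5
    size_min: int = 300
    size_max: int = 8_000
    mssi_fraction: float = 0.2
    include_mito: bool = True
    enzyme_mode: str = "cas9"  # cas9 | mssi | none
    cas9_mito_efficiency: float = 0.86
    reads_per_circle: int = 10
    passes_mean: float = 4.0
    linear_read_count: int = 200
    ghost_read_count: int = 0
    sub_rate: float = 0.01
    ins_rate: float = 0.0025
    del_rate: float = 0.0025
    mean_quality: float = 20.0
    # classification
    min_mapq: int = 1
    min_mean_q: float = 10.0
    min_aligned_fraction: float = 0.3
    min_read_length: int = 200
    same_locus_tolerance: int = 50
    colinear_tolerance: int = 50
    # calling
    min_support: int = 2
    merge_gap: int = 0
    junction_tolerance: int = 20
    # characterization
    size_threshold: int = 3_000
    bin_size: int = 10
    coverage_normalization: str = "rpgc"
    per_million_denominator: str = "filtered"  # filtered | raw

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    def updated(self, **kwargs) -> "RunConfig":
        unknown = set(kwargs) - self.field_names()
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Plain-text key = value configuration; '#' starts a comment."""
        values: dict[str, object] = {}
        hints = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in hints:
                raise ValueError(f"unknown configuration key: {key!r}")
            values[key] = _coerce(val, getattr(cls(), key))
        return cls().updated(**values)

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"


def _coerce(text: str, default):
    if text in ("None", "none", ""):
        return None
    if isinstance(default, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(text)
    if isinstance(default, float):
        return float(text)
    return text


@dataclass
class RunResult:
    outdir: Path
    summary: dict
    calls: list
    truth_circles: list = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every stage, writing all artifacts under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_effective.txt").write_text(config.to_text())
    summary: dict = {"config_seed": config.seed, "group": config.group}
    truth_circles: list = []

    # --- inputs: simulate or load --------------------------------------
    if config.paf is None:
        genome = simulate_mod.generate_genome(
            config.n_chroms, config.chrom_length, config.gc_fraction,
            seed=config.seed, include_mito=config.include_mito,
        )
        track = simulate_mod.plant_annotation(genome, seed=config.seed + 1)
        planted = simulate_mod.sample_circles(
            genome, config.n_simple, config.n_complex,
            size_range=(config.size_min, config.size_max),
            mssi_fraction=config.mssi_fraction,
            include_mito_like=config.include_mito,
            seed=config.seed + 2,
        )
        if config.enzyme_mode in ("cas9", "mssi"):
            truth_circles = simulate_mod.apply_enzyme_model(
                planted, config.enzyme_mode, config.cas9_mito_efficiency,
                seed=config.seed + 3,
            )
        else:
            truth_circles = list(planted)
        readset = simulate_mod.simulate_reads(
            truth_circles, genome, config.reads_per_circle,
            passes_distribution=("geometric", config.passes_mean),
            linear_read_count=config.linear_read_count,
            error_rates=(config.sub_rate, config.ins_rate, config.del_rate),
            seed=config.seed + 4,
            ghost_read_count=config.ghost_read_count,
            mean_quality=config.mean_quality,
        )
        genome.to_fasta(out / "genome.fa")
        genome.write_fai(out / "genome.fa.fai")
        track.to_gff3(out / "annotation.gff3")
        track.to_bed_dir(out / "annotation_bed")
        simulate_mod.write_circle_manifest(planted, out / "truth_circles.tsv")
        readset.write_fastq(out / "reads.fastq")
        readset.write_paf(out / "alignments.paf")
        paf_path = out / "alignments.paf"
        n_raw_reads = len(readset.reads)
        summary["simulated"] = True
        summary["n_planted_circles"] = len(planted)
        summary["n_circles_after_enzyme"] = len(truth_circles)
    else:
        if config.fasta is None:
            raise ValueError("real-data runs need both --paf and --fasta")
        genome = simulate_mod.GenomeRef.from_fasta(config.fasta)
        track = (
            annotate_mod.AnnotationTrack.from_gff3(config.annotation_gff)
            if config.annotation_gff
            else None
        )
        paf_path = Path(config.paf)
        n_raw_reads = None
        summary["simulated"] = False

    # --- classify -------------------------------------------------------
    profiles = classify_mod.load_alignments(paf_path, min_mapq=config.min_mapq)
    kept, n_ghost_filtered = classify_mod.filter_reads(
        profiles,
        min_mean_q=config.min_mean_q,
        min_aligned_fraction=config.min_aligned_fraction,
        min_read_length=config.min_read_length,
    )
    if n_raw_reads is None:
        n_raw_reads = len(profiles)
    n_ghost_unaligned = n_raw_reads - len(profiles)
    labels: dict[str, str] = {}
    implied: dict[str, int] = {}
    for p in kept:
        lab = classify_mod.classify_read(
            p,
            same_locus_tolerance=config.same_locus_tolerance,
            colinear_tolerance=config.colinear_tolerance,
        )
        labels[p.read_id] = lab
        if lab == "ctc":
            implied[p.read_id] = trim_ctc(p, tolerance=config.same_locus_tolerance).implied_length
    with open(out / "read_labels.tsv", "w") as fh:
        fh.write("read_id\tlabel\tn_blocks\timplied_length\n")
        for p in kept:
            fh.write(
                f"{p.read_id}\t{labels[p.read_id]}\t{len(p.blocks)}\t"
                f"{implied.get(p.read_id, '')}\n"
            )
    class_counts = {lab: 0 for lab in ("normal", "breakpoint", "ctc")}
    for lab in labels.values():
        class_counts[lab] += 1
    summary["reads"] = {
        "total": n_raw_reads,
        "ghost_unaligned": n_ghost_unaligned,
        "ghost_filtered": n_ghost_filtered,
        "retained": len(kept),
        **class_counts,
    }

    # --- call -----------------------------------------------------------
    calls = call_all(
        kept, genome,
        min_support=config.min_support,
        merge_gap=config.merge_gap,
        junction_tolerance=config.junction_tolerance,
        same_locus_tolerance=config.same_locus_tolerance,
        colinear_tolerance=config.colinear_tolerance,
        labels=labels,
    )
    _write_calls(calls, out)
    summary["n_calls"] = len(calls)

    # --- annotate -------------------------------------------------------
    if track is not None and calls:
        summaries = [annotate_mod.annotate_call(c, track) for c in calls]
        agg = annotate_mod.aggregate_composition(summaries, [config.group] * len(summaries))
        rows = []
        for s in summaries:
            row = {"ecc_id": s.ecc_id, "total_length": s.total_length}
            for cls in annotate_mod.FEATURE_CLASSES:
                row[f"{cls}_count"] = s.count(cls)
                row[f"{cls}_bases"] = s.overlap_bases(cls)
            rows.append(row)
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "composition_per_call.tsv", sep="\t", index=False)
        agg.table.to_csv(out / "composition_aggregate.tsv", sep="\t", index=False)
        summary["intron_exon_ratio"] = agg.intron_exon_ratio.get(config.group)

    # --- characterize ---------------------------------------------------
    chrom_lengths = genome.lengths
    if calls:
        sizes = stats_mod.size_distribution(
            calls, [config.group] * len(calls), threshold=config.size_threshold
        )
        sizes.to_csv(out / "size_stats.tsv", sep="\t", index=False)
        summary["fraction_below_threshold"] = float(sizes["fraction_below"].iloc[0])
        chrom_dist = stats_mod.chrom_distribution(calls, chrom_lengths)
        chrom_dist.to_csv(out / "chrom_distribution.tsv", sep="\t", index=False)
        forms = stats_mod.form_proportions(calls, [config.group] * len(calls))
        forms.to_csv(out / "form_proportions.tsv", sep="\t", index=False)
        summary["simple_fraction"] = float(forms["simple_fraction"].iloc[0])
        summary["complex_fraction"] = float(forms["complex_fraction"].iloc[0])
        site_rows = []
        n_with_site = 0
        for c in calls:
            hits = stats_mod.scan_recognition_sites(c.sequence, circular=True)
            n_with_site += bool(hits)
            site_rows.append((c.ecc_id, len(hits), ",".join(map(str, hits))))
        with open(out / "site_census.tsv", "w") as fh:
            fh.write("ecc_id\tn_sites\tpositions\n")
            for row in site_rows:
                fh.write("\t".join(map(str, row)) + "\n")
        summary["n_calls_with_mssi_site"] = n_with_site
    denominator = len(kept) if config.per_million_denominator == "filtered" else n_raw_reads
    summary["ecc_per_million_reads"] = (
        stats_mod.normalize_per_million(len(calls), denominator) if denominator else None
    )
    retained_blocks = [b for p in kept for b in p.blocks]
    if retained_blocks:
        trackcov = stats_mod.coverage_track(
            retained_blocks, chrom_lengths,
            bin_size=config.bin_size, normalization=config.coverage_normalization,
        )
        trackcov.to_bedgraph(out / "coverage.bedgraph")

    # --- summary and manifest -------------------------------------------
    summary["genome_sha256"] = hashlib.sha256(
        "".join(genome.sequences.values()).encode()
    ).hexdigest()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest_lines = []
    for p in sorted(out.rglob("*")):
        if p.name == "manifest.txt" or p.is_dir():
            continue
        manifest_lines.append(f"{_sha256(p)}  {p.relative_to(out)}")
    (out / "manifest.txt").write_text("\n".join(manifest_lines) + "\n")
    return RunResult(out, summary, calls, truth_circles)


def _write_calls(calls, out: Path) -> None:
    with open(out / "calls.bed", "w") as fh:
        for c in calls:
            for fi, (chrom, s, e, strand) in enumerate(c.fragments):
                fh.write(f"{chrom}\t{s}\t{e}\t{c.ecc_id}\t{fi}\t{strand}\n")
    with open(out / "calls_manifest.tsv", "w") as fh:
        fh.write("ecc_id\tform\ttotal_length\tn_reads\tmean_depth\tn_fragments\n")
        for c in calls:
            fh.write(
                f"{c.ecc_id}\t{c.form}\t{c.total_length}\t{c.n_reads}\t"
                f"{c.mean_depth:.3f}\t{len(c.fragments)}\n"
            )
    with open(out / "calls.fasta", "w") as fh:
        for c in calls:
            fh.write(f">{c.ecc_id} length={c.total_length} form={c.form}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")


def compare_groups(run_a: str | Path, run_b: str | Path) -> dict:
    """Side-by-side contrast of two completed runs.

    Both runs must share the same reference (genome checksum); the report
    juxtaposes read-class counts, call counts, form proportions, the
    below-threshold size fraction and site census.
    """
    a = json.loads((Path(run_a) / "summary.json").read_text())
    b = json.loads((Path(run_b) / "summary.json").read_text())
    if a.get("genome_sha256") != b.get("genome_sha256"):
        raise ValueError("runs use different references; contrast is not meaningful")
    keys = [
        "n_calls", "simple_fraction", "complex_fraction",
        "fraction_below_threshold", "n_calls_with_mssi_site",
        "ecc_per_million_reads", "intron_exon_ratio",
    ]
    contrast = {"run_a": str(run_a), "run_b": str(run_b)}
    for k in keys:
        contrast[k] = {"a": a.get(k), "b": b.get(k)}
    contrast["reads"] = {"a": a.get("reads"), "b": b.get("reads")}
    return contrast
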