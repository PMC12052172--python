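"""Circle reconstruction from classified read profiles.

Stage 2 merges the aligned blocks of retained reads into genomic regions
and turns breakpoint junctions into linkages between regions.  Stage 3
represents regions as nodes and linkages as edges of a breakpoint graph,
confirms circularity by finding simple cycles whose every edge has
enough read support, and extracts each circle's sequence from the
reference, with fragment boundaries refined to the median junction
offset over the supporting reads.

Linkage endpoints are (region, side) pairs, ``side`` being the low
("left") or high ("right") coordinate flank of a region.  Traversing a
region forward enters on the left and exits on the right; a consistent
circular walk must alternate sides, which excludes foldback junctions.
"""
from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median

import networkx as nx

from ._seq import revcomp
from .classify import AlignmentBlock, ReadProfile, classify_read, colinear, trim_ctc

__all__ = [
    "Region",
    "Linkage",
    "RegionGraph",
    "Cycle",
    "EccDNACall",
    "merge_regions",
    "build_linkages",
    "build_region_graph",
    "find_circles",
    "assemble_call",
    "call_all",
]


@dataclass(frozen=True)
class Region:
    region_id: str
    chrom: str
    start: int
    end: int
    n_supporting_blocks: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: start >= end")


@dataclass
class Linkage:
    """An aggregated breakpoint junction between two region flanks."""

    endpoint_a: tuple[str, str]  # (region_id, "left"|"right")
    endpoint_b: tuple[str, str]
    offsets_a: list[int] = field(default_factory=list)
    offsets_b: list[int] = field(default_factory=list)
    read_ids: set[str] = field(default_factory=set)

    @property
    def n_supporting_reads(self) -> int:
        return len(self.read_ids)

    @property
    def regions(self) -> tuple[str, str]:
        return self.endpoint_a[0], self.endpoint_b[0]


@dataclass
class RegionGraph:
    regions: dict[str, Region]
    linkages: list[Linkage]

    def __post_init__(self) -> None:
        for l in self.linkages:
            for rid, _side in (l.endpoint_a, l.endpoint_b):
                if rid not in self.regions:
                    raise ValueError(f"linkage endpoint {rid} not among regions")


@dataclass
class Cycle:
    """An oriented circular walk: regions[i] is left via linkages[i] into
    regions[(i+1) % n]."""

    regions: list[tuple[Region, str]]  # (region, orientation)
    linkages: list[Linkage]

    @property
    def total_support(self) -> int:
        return sum(l.n_supporting_reads for l in self.linkages)


@dataclass
class EccDNACall:
    ecc_id: str
    fragments: list[tuple[str, int, int, str]]
    n_reads: int
    mean_depth: float
    sequence: str

    def __post_init__(self) -> None:
        if self.total_length != len(self.sequence):
            raise ValueError(
                f"{self.ecc_id}: sequence length {len(self.sequence)} != "
                f"fragment total {self.total_length}"
            )

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e, _ in self.fragments)

    @property
    def form(self) -> str:
        return "simple" if len({c for c, *_ in self.fragments}) == 1 else "complex"


# ---------------------------------------------------------------------------
# stage 2: regions and linkages


def merge_regions(blocks: list[AlignmentBlock], merge_gap: int = 0) -> list[Region]:
    """Merge aligned blocks into regions per chromosome (sort-and-sweep).

    Blocks closer than or equal to ``merge_gap`` (default 0: touching or
    overlapping) merge; each region records how many blocks it absorbed.
    Output is deterministic, sorted by (chrom, start).
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for b in blocks:
        by_chrom[b.chrom].append((b.ref_start, b.ref_end))
    regions: list[Region] = []
    idx = 0
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e, n = ivs[0][0], ivs[0][1], 1
        for s, e in ivs[1:]:
            if s <= cur_e + merge_gap:
                cur_e = max(cur_e, e)
                n += 1
            else:
                regions.append(Region(f"R{idx:05d}", chrom, cur_s, cur_e, n))
                idx += 1
                cur_s, cur_e, n = s, e, 1
        regions.append(Region(f"R{idx:05d}", chrom, cur_s, cur_e, n))
        idx += 1
    return regions


class _RegionIndex:
    def __init__(self, regions: list[Region]):
        self.by_chrom: dict[str, tuple[list[int], list[Region]]] = {}
        grouped: dict[str, list[Region]] = defaultdict(list)
        for r in regions:
            grouped[r.chrom].append(r)
        for chrom, rs in grouped.items():
            rs.sort(key=lambda r: r.start)
            self.by_chrom[chrom] = ([r.start for r in rs], rs)

    def assign(self, block: AlignmentBlock) -> Region:
        if block.chrom not in self.by_chrom:
            raise ValueError(f"block on {block.chrom} matches no region")
        starts, rs = self.by_chrom[block.chrom]
        i = bisect_right(starts, block.ref_start) - 1
        if i < 0 or rs[i].end < block.ref_end:
            raise ValueError(
                f"block {block.chrom}:{block.ref_start}-{block.ref_end} not contained "
                "in a single merged region"
            )
        return rs[i]


def _junction(a: AlignmentBlock, b: AlignmentBlock, index: _RegionIndex):
    """The breakpoint implied by read-adjacent blocks a -> b: the flank of
    a's region that is exited and the flank of b's region that is entered,
    with the junction offsets on the reference."""
    ra, rb = index.assign(a), index.assign(b)
    if a.strand == "+":
        side_a, off_a = "right", a.ref_end
    else:
        side_a, off_a = "left", a.ref_start
    if b.strand == "+":
        side_b, off_b = "left", b.ref_start
    else:
        side_b, off_b = "right", b.ref_end
    return (ra.region_id, side_a, off_a), (rb.region_id, side_b, off_b)


def _ref_contiguous(a: AlignmentBlock, b: AlignmentBlock, tol: int) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.strand == "+":
        return abs(b.ref_start - a.ref_end) <= tol
    return abs(a.ref_start - b.ref_end) <= tol


def build_linkages(
    profiles: list[tuple[ReadProfile, str]],
    regions: list[Region],
    junction_tolerance: int = 20,
    colinear_tolerance: int = 50,
) -> list[Linkage]:
    """Aggregate per-read junctions into region linkages.

    ``profiles`` are (profile, label) pairs; only breakpoint and ctc reads
    contribute (ctc profiles must already be trimmed to one pass).  Every
    non-colinear consecutive block pair emits a junction; ctc reads add
    the wrap-around pair (last block -> first block) unless it merely
    continues the same locus, closing single-region circles.  Junctions
    with the same endpoint pair and offsets within ``junction_tolerance``
    aggregate with summed support.
    """
    index = _RegionIndex(regions)
    raw: dict[tuple, list[tuple[int, int, str]]] = defaultdict(list)
    for profile, label in profiles:
        if label not in ("breakpoint", "ctc"):
            continue
        blocks = profile.sorted_blocks()
        pairs = list(zip(blocks, blocks[1:]))
        for a, b in pairs:
            if colinear(a, b, colinear_tolerance):
                continue
            ea, eb = _junction(a, b, index)
            _record(raw, ea, eb, profile.read_id)
        if label == "ctc" and blocks:
            a, b = blocks[-1], blocks[0]
            if len(blocks) == 1 or not _ref_contiguous(a, b, colinear_tolerance):
                ea, eb = _junction(a, b, index)
                _record(raw, ea, eb, profile.read_id)
    linkages: list[Linkage] = []
    for key, recs in sorted(raw.items()):
        linkages.extend(_cluster(key, recs, junction_tolerance))
    return linkages


def _record(raw, ea, eb, read_id):
    (rid_a, side_a, off_a), (rid_b, side_b, off_b) = ea, eb
    # canonical endpoint order so A->B and B->A traversals aggregate
    if (rid_b, side_b) < (rid_a, side_a):
        ea, eb = eb, ea
        off_a, off_b = off_b, off_a
        rid_a, side_a, rid_b, side_b = rid_b, side_b, rid_a, side_a
    raw[((rid_a, side_a), (rid_b, side_b))].append((off_a, off_b, read_id))


def _cluster(key, recs, tol: int) -> list[Linkage]:
    ea, eb = key
    recs = sorted(recs)
    clusters: list[Linkage] = []
    for off_a, off_b, read_id in recs:
        placed = False
        for c in clusters:
            if (
                abs(off_a - median(c.offsets_a)) <= tol
                and abs(off_b - median(c.offsets_b)) <= tol
            ):
                c.offsets_a.append(off_a)
                c.offsets_b.append(off_b)
                c.read_ids.add(read_id)
                placed = True
                break
        if not placed:
            clusters.append(Linkage(ea, eb, [off_a], [off_b], {read_id}))
    return clusters


def build_region_graph(regions: list[Region], linkages: list[Linkage]) -> RegionGraph:
    return RegionGraph({r.region_id: r for r in regions}, linkages)


# ---------------------------------------------------------------------------
# stage 3: cycle finding and assembly

_EXIT = {"+": "right", "-": "left"}
_ENTRY = {"+": "left", "-": "right"}
_FLIP = {"+": "-", "-": "+"}


def _walk_cycles(
    nodes: list[str], edges_by_pair, graph: RegionGraph, max_realizations: int = 1_000
) -> list[Cycle]:
    """Every orientation-consistent realization of a node cycle, one per
    distinct edge choice (parallel linkages between the same regions give
    distinct candidates so the best-supported one can win)."""
    k = len(nodes)
    pairs = [tuple(sorted((nodes[i], nodes[(i + 1) % k]))) for i in range(k)]
    found: dict[tuple[int, ...], Cycle] = {}

    def step(i: int, orient: list[str], chosen: list[Linkage]) -> None:
        if len(found) >= max_realizations:
            return
        if i == k:
            key = tuple(sorted(id(l) for l in chosen))
            found.setdefault(
                key, Cycle([(graph.regions[n], o) for n, o in zip(nodes, orient)], chosen)
            )
            return
        a, b = nodes[i], nodes[(i + 1) % k]
        for link in edges_by_pair.get(pairs[i], ()):
            if any(link is c for c in chosen):
                continue
            for (r1, s1), (r2, s2) in (
                (link.endpoint_a, link.endpoint_b),
                (link.endpoint_b, link.endpoint_a),
            ):
                if r1 != a or r2 != b:
                    continue
                if s1 != _EXIT[orient[i]]:
                    continue
                o_next = "+" if s2 == "left" else "-"
                j = (i + 1) % k
                if j == 0:  # closing edge must agree with the start orientation
                    if o_next != orient[0]:
                        continue
                    step(i + 1, orient, chosen + [link])
                else:
                    new_orient = list(orient)
                    new_orient[j] = o_next
                    step(i + 1, new_orient, chosen + [link])

    for o0 in ("+", "-"):
        step(0, [o0] + ["+"] * (k - 1), [])
    return list(found.values())


def find_circles(graph: RegionGraph, min_support: int = 2) -> list[Cycle]:
    """Edge-disjoint simple cycles whose every edge has read support >=
    ``min_support``; each region participates in at most one reported
    cycle (greedy assignment by descending total support, ties broken by
    the smaller genomic coordinate).  Non-cyclic components yield nothing.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    strong = [l for l in graph.linkages if l.n_supporting_reads >= min_support]
    if not strong:
        return []
    G = nx.MultiGraph()
    G.add_nodes_from(graph.regions)
    edges_by_pair: dict[tuple[str, str], list[Linkage]] = defaultdict(list)
    for l in strong:
        ra, rb = l.regions
        G.add_edge(ra, rb)
        edges_by_pair[tuple(sorted((ra, rb)))].append(l)
    candidates: list[Cycle] = []
    seen_sets: set[frozenset] = set()
    for nodes in nx.simple_cycles(G):
        key = frozenset(nodes)
        if key in seen_sets:
            continue
        seen_sets.add(key)
        candidates.extend(_walk_cycles(list(nodes), edges_by_pair, graph))

    def sort_key(c: Cycle):
        coord = min((r.chrom, r.start) for r, _ in c.regions)
        return (-c.total_support, coord)

    candidates.sort(key=sort_key)
    used_regions: set[str] = set()
    used_edges: list[Linkage] = []
    chosen: list[Cycle] = []
    for c in candidates:
        rids = {r.region_id for r, _ in c.regions}
        if rids & used_regions:
            continue
        if any(any(l is u for u in used_edges) for l in c.linkages):
            continue
        chosen.append(c)
        used_regions |= rids
        used_edges.extend(c.linkages)
    return chosen


def _refined_fragments(cycle: Cycle) -> list[tuple[str, int, int, str]]:
    """Fragment spans refined to the median junction offset on each flank."""
    offsets: dict[tuple[str, str], list[int]] = defaultdict(list)
    for link in cycle.linkages:
        offsets[link.endpoint_a].extend(link.offsets_a)
        offsets[link.endpoint_b].extend(link.offsets_b)
    frags = []
    for region, orient in cycle.regions:
        left = offsets.get((region.region_id, "left"))
        right = offsets.get((region.region_id, "right"))
        start = int(round(median(left))) if left else region.start
        end = int(round(median(right))) if right else region.end
        if start >= end:
            start, end = region.start, region.end
        frags.append((region.chrom, start, end, orient))
    return frags


def _canonical_rotation(
    frags: list[tuple[str, int, int, str]]
) -> list[tuple[str, int, int, str]]:
    """Start at the lexicographically smallest (chrom, start) fragment in
    forward orientation; circles have no intrinsic start, so this fixes a
    reporting convention."""
    i0 = min(range(len(frags)), key=lambda i: (frags[i][0], frags[i][1], frags[i][2]))
    if frags[i0][3] == "-":
        frags = [(c, s, e, _FLIP[st]) for c, s, e, st in reversed(frags)]
        i0 = min(range(len(frags)), key=lambda i: (frags[i][0], frags[i][1], frags[i][2]))
    return frags[i0:] + frags[:i0]


def assemble_call(
    cycle: Cycle,
    genome,
    profiles_by_read: dict[str, ReadProfile],
    ecc_id: str = "ecc",
) -> EccDNACall:
    """Reference-guided extraction of one eccDNA call from a cycle.

    The sequence is the concatenation of fragment reference sequences in
    cycle order and orientation (reverse-complement for minus strands).
    ``n_reads`` counts distinct reads contributing any edge; mean depth is
    total aligned bases of supporting reads within the fragments divided
    by the circle length (a fold-coverage).
    """
    frags = _canonical_rotation(_refined_fragments(cycle))
    parts = []
    for chrom, s, e, strand in frags:
        seq = genome.fetch(chrom, s, e)
        parts.append(revcomp(seq) if strand == "-" else seq)
    sequence = "".join(parts)
    support_reads = set()
    for link in cycle.linkages:
        support_reads |= link.read_ids
    total_len = sum(e - s for _, s, e, _ in frags)
    aligned = 0
    for rid in support_reads:
        prof = profiles_by_read.get(rid)
        if prof is None:
            continue
        for b in prof.blocks:
            for chrom, s, e, _ in frags:
                if b.chrom == chrom:
                    aligned += max(0, min(b.ref_end, e) - max(b.ref_start, s))
    mean_depth = aligned / total_len if total_len else 0.0
    return EccDNACall(ecc_id, frags, len(support_reads), mean_depth, sequence)


# ---------------------------------------------------------------------------
# orchestration


def call_all(
    profiles: list[ReadProfile],
    genome,
    *,
    min_support: int = 2,
    merge_gap: int = 0,
    junction_tolerance: int = 20,
    same_locus_tolerance: int = 50,
    colinear_tolerance: int = 50,
    labels: dict[str, str] | None = None,
) -> list[EccDNACall]:
    """Classify (unless labels are given), trim CTC reads, merge regions,
    build linkages, find cycles and assemble calls — deterministic, sorted
    by the canonical fragment's (chrom, start)."""
    if not profiles:
        return []
    working: list[tuple[ReadProfile, str]] = []
    for p in profiles:
        lab = labels.get(p.read_id) if labels else classify_read(
            p, same_locus_tolerance=same_locus_tolerance, colinear_tolerance=colinear_tolerance
        )
        if lab == "ghost":
            continue
        if lab == "ctc":
            working.append((trim_ctc(p, tolerance=same_locus_tolerance), "ctc"))
        else:
            working.append((p, lab))
    # regions come from junction-evidencing reads only: blocks of normal
    # (linear-consistent) reads carry no circularity signal, and merging
    # them in can chain distinct circle loci into one region
    blocks = [b for p, lab in working if lab in ("breakpoint", "ctc") for b in p.blocks]
    if not blocks:
        return []
    regions = merge_regions(blocks, merge_gap)
    linkages = build_linkages(
        working, regions, junction_tolerance=junction_tolerance,
        colinear_tolerance=colinear_tolerance,
    )
    graph = build_region_graph(regions, linkages)
    cycles = find_circles(graph, min_support=min_support)
    by_read = {p.read_id: p for p in profiles}
    calls = [assemble_call(c, genome, by_read) for c in cycles]
    calls.sort(key=lambda c: (c.fragments[0][0], c.fragments[0][1], c.fragments[0][2]))
    return [
        EccDNACall(f"ecc{i:04d}", c.fragments, c.n_reads, c.mean_depth, c.sequence)
        for i, c in enumerate(calls)
    ]
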