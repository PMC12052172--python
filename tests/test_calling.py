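"""Region merging, breakpoint-linkage aggregation, cycle finding and
reference-guided call assembly."""
import numpy as np
import pytest

import ecclong as e
from ecclong import calling
from ecclong.classify import AlignmentBlock, ReadProfile
from ecclong.simulate import TruthCircle


def blk(qs, qe, chrom, rs, re, strand="+", qlen=100_000, rid="r"):
    return AlignmentBlock(rid, qs, qe, chrom, rs, re, strand, 60, qlen)


def merge_oracle(intervals_by_chrom, gap=0):
    """Coverage-array oracle: paint every interval (widened by the gap on
    the right) onto a boolean axis and read off maximal runs."""
    out = []
    for chrom, ivs in sorted(intervals_by_chrom.items()):
        hi = max(end for _, end in ivs) + gap + 2
        cov = np.zeros(hi, dtype=bool)
        for s, end in ivs:
            cov[s : end + gap] = True
        padded = np.concatenate(([False], cov, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, end in zip(starts, ends):
            out.append((chrom, int(s), int(end - gap) if gap else int(end)))
    return out


class TestMergeRegions:
    def test_empty(self):
        assert calling.merge_regions([]) == []

    def test_basic_example(self):
        blocks = [
            blk(0, 100, "chr1", 100, 200),
            blk(0, 100, "chr1", 150, 250),
            blk(0, 100, "chr1", 400, 500),
        ]
        regions = calling.merge_regions(blocks)
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("chr1", 100, 250), ("chr1", 400, 500)
        ]
        assert [r.n_supporting_blocks for r in regions] == [2, 1]

    def test_touching_intervals_merge_at_gap_zero(self):
        blocks = [blk(0, 100, "chr1", 100, 200), blk(0, 100, "chr1", 200, 300)]
        regions = calling.merge_regions(blocks, merge_gap=0)
        assert len(regions) == 1 and (regions[0].start, regions[0].end) == (100, 300)

    @pytest.mark.parametrize("gap", [0, 10])
    def test_hypothesis_interval_lists_match_oracle(self, gap):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        interval = st.tuples(st.integers(0, 5_000), st.integers(1, 300))

        @settings(max_examples=50, derandomize=True, deadline=None)
        @given(st.lists(interval, min_size=1, max_size=60))
        def check(raw):
            ivs = [(s, s + w) for s, w in raw]
            blocks = [blk(0, 10, "chr1", s, t) for s, t in ivs]
            got = [(r.chrom, r.start, r.end) for r in calling.merge_regions(blocks, gap)]
            assert got == merge_oracle({"chr1": ivs}, gap)

        check()

    @pytest.mark.parametrize("gap", [0, 10])
    def test_random_against_coverage_oracle(self, gap):
        rng = np.random.default_rng(42)
        blocks = []
        by_chrom = {}
        for _ in range(10_000):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 50_000))
            end = s + int(rng.integers(1, 500))
            blocks.append(blk(0, 100, chrom, s, end))
            by_chrom.setdefault(chrom, []).append((s, end))
        got = [(r.chrom, r.start, r.end) for r in calling.merge_regions(blocks, gap)]
        assert got == merge_oracle(by_chrom, gap)

    def test_deterministic_order(self):
        blocks = [blk(0, 100, "chr2", 0, 10), blk(0, 100, "chr1", 5, 15)]
        regions = calling.merge_regions(blocks)
        assert [r.chrom for r in regions] == ["chr1", "chr2"]


class TestBuildLinkages:
    def test_single_region_ctc_self_linkage(self):
        p = ReadProfile("r1", 2000, [
            blk(0, 1000, "chr1", 1000, 2000, rid="r1", qlen=2000),
            blk(1000, 2000, "chr1", 1000, 2000, rid="r1", qlen=2000),
        ], ctc_trimmed=False)
        t = e.trim_ctc(p)
        regions = calling.merge_regions(t.blocks)
        links = calling.build_linkages([(t, "ctc")], regions)
        assert len(links) == 1
        l = links[0]
        assert l.endpoint_a == (regions[0].region_id, "left")
        assert l.endpoint_b == (regions[0].region_id, "right")
        assert l.n_supporting_reads == 1

    def test_rotations_aggregate_to_one_cycle_support_two(self):
        p1 = ReadProfile("r1", 2000, [
            blk(0, 1000, "chr1", 5000, 6000, rid="r1", qlen=2000),
            blk(1000, 2000, "chr2", 800, 1800, rid="r1", qlen=2000),
        ], ctc_trimmed=True)
        p2 = ReadProfile("r2", 2000, [
            blk(0, 1000, "chr2", 800, 1800, rid="r2", qlen=2000),
            blk(1000, 2000, "chr1", 5000, 6000, rid="r2", qlen=2000),
        ], ctc_trimmed=True)
        regions = calling.merge_regions([b for p in (p1, p2) for b in p.blocks])
        links = calling.build_linkages([(p1, "ctc"), (p2, "ctc")], regions)
        assert len(links) == 2
        assert all(l.n_supporting_reads == 2 for l in links)

    def test_normal_profiles_make_no_linkages(self):
        p = ReadProfile("r1", 1000, [blk(0, 1000, "chr1", 0, 1000, rid="r1", qlen=1000)])
        regions = calling.merge_regions(p.blocks)
        assert calling.build_linkages([(p, "normal")], regions) == []

    def test_offset_clusters_split_beyond_tolerance(self):
        def bp_read(rid, j):
            return ReadProfile(rid, 2000, [
                blk(0, 1000, "chr1", 4000, 5000 + j, rid=rid, qlen=2000),
                blk(1000, 2000, "chr1", 9000, 10_000, rid=rid, qlen=2000),
            ])
        near = [(bp_read("a", 0), "breakpoint"), (bp_read("b", 5), "breakpoint")]
        far = [(bp_read("c", 500), "breakpoint")]
        regions = calling.merge_regions([b for p, _ in near + far for b in p.blocks])
        links = calling.build_linkages(near + far, regions, junction_tolerance=20)
        assert sorted(l.n_supporting_reads for l in links) == [1, 2]


class TestFindCircles:
    def _graph(self, regions, links):
        return calling.build_region_graph(regions, links)

    def test_self_loop_single_fragment_cycle(self):
        r = calling.Region("R0", "chr1", 1000, 2000, 5)
        l = calling.Linkage(("R0", "left"), ("R0", "right"), [1000] * 5, [2000] * 5,
                            {f"r{i}" for i in range(5)})
        cycles = calling.find_circles(self._graph([r], [l]), min_support=2)
        assert len(cycles) == 1
        assert [(reg.region_id, o) for reg, o in cycles[0].regions] == [("R0", "+")]

    def test_two_region_cycle(self):
        ra = calling.Region("Ra", "chr1", 0, 1000, 4)
        rb = calling.Region("Rb", "chr2", 0, 1000, 4)
        l1 = calling.Linkage(("Ra", "right"), ("Rb", "left"), [1000] * 2, [0] * 2, {"r1", "r2"})
        l2 = calling.Linkage(("Ra", "left"), ("Rb", "right"), [0] * 2, [1000] * 2, {"r1", "r2"})
        cycles = calling.find_circles(self._graph([ra, rb], [l1, l2]), min_support=2)
        assert len(cycles) == 1
        assert len(cycles[0].regions) == 2

    def test_support_below_threshold_no_cycle(self):
        r = calling.Region("R0", "chr1", 1000, 2000, 1)
        l = calling.Linkage(("R0", "left"), ("R0", "right"), [1000], [2000], {"r1"})
        assert calling.find_circles(self._graph([r], [l]), min_support=2) == []

    def test_foldback_junction_is_not_a_circle(self):
        r = calling.Region("R0", "chr1", 1000, 2000, 5)
        l = calling.Linkage(("R0", "right"), ("R0", "right"), [2000] * 3, [2000] * 3,
                            {"r1", "r2", "r3"})
        assert calling.find_circles(self._graph([r], [l]), min_support=2) == []

    def test_region_in_at_most_one_cycle(self):
        # one region with two competing self-loop junctions: only the
        # better-supported cycle is reported
        r = calling.Region("R0", "chr1", 1000, 3000, 9)
        strong = calling.Linkage(("R0", "left"), ("R0", "right"), [1000] * 6, [3000] * 6,
                                 {f"s{i}" for i in range(6)})
        weak = calling.Linkage(("R0", "left"), ("R0", "right"), [1500] * 2, [2500] * 2,
                               {"w1", "w2"})
        cycles = calling.find_circles(self._graph([r], [strong, weak]), min_support=2)
        assert len(cycles) == 1
        assert cycles[0].total_support == 6


class TestAssembleCall:
    def test_single_fragment_sequence_extraction(self, genome):
        r = calling.Region("R0", "chr1", 1000, 2100, 5)
        l = calling.Linkage(("R0", "left"), ("R0", "right"), [1000] * 3, [2000] * 3,
                            {"r1", "r2", "r3"})
        cycle = calling.find_circles(calling.build_region_graph([r], [l]), 2)[0]
        call = calling.assemble_call(cycle, genome, {})
        assert call.fragments == [("chr1", 1000, 2000, "+")]  # refined to junction medians
        assert call.sequence == genome.fetch("chr1", 1000, 2000)
        assert call.total_length == 1000
        assert call.form == "simple"

    def test_mean_depth_tracks_pass_count(self, genome):
        circle = TruthCircle("c", [("chr3", 100_000, 101_000, "+")])
        rs = e.simulate_reads([circle], genome, 10, ("fixed", 10),
                              error_rates=(0, 0, 0), seed=4)
        profiles = e.load_alignments(rs.paf_lines())
        calls = e.call_all(profiles, genome)
        assert len(calls) == 1
        assert abs(calls[0].mean_depth - 100) <= 10  # 10 reads x 10 passes
        assert calls[0].n_reads == 10

    def test_canonical_rotation_invariance(self):
        frags = [("chr2", 50, 80, "+"), ("chr1", 100, 200, "+"), ("chr3", 10, 40, "-")]
        rotated = frags[1:] + frags[:1]
        reversed_ = [(c, s, t, {"+": "-", "-": "+"}[st]) for c, s, t, st in reversed(frags)]
        canon = calling._canonical_rotation
        assert canon(list(frags)) == canon(rotated) == canon(reversed_)
        assert canon(list(frags))[0][0] == "chr1"


class TestCallAll:
    def test_empty_profiles_empty_calls(self, genome):
        assert e.call_all([], genome) == []

    def test_conservation_invariant(self, genome, clean_profiles):
        for call in e.call_all(clean_profiles, genome):
            span_sum = sum(fe - fs for _, fs, fe, _ in call.fragments)
            assert call.total_length == span_sum == len(call.sequence)

    def test_support_monotonicity(self, genome, nuclear_circles):
        rs = e.simulate_reads(nuclear_circles, genome, 4, ("geometric", 4.0),
                              linear_read_count=100,
                              error_rates=(0.01, 0.0025, 0.0025), seed=31)
        profiles, _ = e.filter_reads(e.load_alignments(rs.paf_lines()))
        counts = [len(e.call_all(profiles, genome, min_support=m)) for m in (1, 2, 3, 5, 10)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_output(self, genome, clean_profiles):
        a = e.call_all(clean_profiles, genome)
        b = e.call_all(clean_profiles, genome)
        assert [(c.ecc_id, c.fragments, c.sequence) for c in a] == [
            (c.ecc_id, c.fragments, c.sequence) for c in b
        ]

    def test_calls_sorted_by_canonical_fragment(self, genome, clean_profiles):
        calls = e.call_all(clean_profiles, genome)
        keys = [(c.fragments[0][0], c.fragments[0][1]) for c in calls]
        assert keys == sorted(keys)
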