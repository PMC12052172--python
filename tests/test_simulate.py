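"""The synthetic-data generator: determinism, planted-truth consistency,
concatemer arithmetic and the enzymatic depletion model."""
import io

import numpy as np
import pytest

import ecclong as e
from ecclong.simulate import MSSI_SITE, TruthCircle, write_circle_manifest


def _fasta_bytes(genome):
    buf = io.StringIO()
    for name, seq in genome.sequences.items():
        buf.write(f">{name}\n{seq}\n")
    return buf.getvalue()


class TestGenerateGenome:
    def test_lengths_and_names(self):
        g = e.generate_genome(2, 100_000, 0.40, seed=1)
        assert g.chrom_names == ["chr1", "chr2"]
        assert all(length == 100_000 for length in g.lengths.values())

    def test_seed_determinism(self, tmp_path):
        g1 = e.generate_genome(2, 100_000, 0.40, seed=1)
        g2 = e.generate_genome(2, 100_000, 0.40, seed=1)
        g1.to_fasta(tmp_path / "a.fa")
        g2.to_fasta(tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        g3 = e.generate_genome(2, 100_000, 0.40, seed=2)
        assert _fasta_bytes(g1) != _fasta_bytes(g3)

    def test_gc_content_near_target(self):
        g = e.generate_genome(5, 400_000, 0.39, seed=7)
        assert 0.37 <= g.gc_content() <= 0.41

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_chroms=1, chrom_length=100_000, gc_fraction=0.4), "n_chroms"),
            (dict(n_chroms=2, chrom_length=10_000, gc_fraction=0.4), "chrom_length"),
            (dict(n_chroms=2, chrom_length=100_000, gc_fraction=1.5), "gc_fraction"),
        ],
    )
    def test_invalid_parameters_name_the_parameter(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            e.generate_genome(seed=1, **kwargs)

    def test_mito_contig(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=1, include_mito=True)
        assert g.lengths["chrM_sim"] == 16_500

    def test_fasta_roundtrip(self, tmp_path):
        g = e.generate_genome(2, 100_000, 0.4, seed=5)
        g.to_fasta(tmp_path / "g.fa")
        g2 = e.GenomeRef.from_fasta(tmp_path / "g.fa")
        assert g2.sequences == g.sequences


class TestPlantAnnotation:
    def test_zero_densities_empty_track(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=1)
        cfg = {cls: {"density": 0.0, "length": (100, 200)} for cls in ("gene", "SINE")}
        assert len(e.plant_annotation(g, cfg, seed=0)) == 0

    def test_gene_partition_tiles_exactly(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=1)
        cfg = {"gene": {"density": 10.0, "length": (10_000, 10_000), "exons": (3, 3)}}
        track = e.plant_annotation(g, cfg, seed=4)
        df = track.to_frame()
        for _, gene in df[df.feature_class == "gene"].iterrows():
            parts = df[
                (df.feature_class.isin(["exon", "intron"]))
                & (df.chrom == gene.chrom)
                & (df.start >= gene.start)
                & (df.end <= gene.end)
            ].sort_values("start")
            assert parts.iloc[0].start == gene.start
            assert parts.iloc[-1].end == gene.end
            # contiguous, non-overlapping tiling
            assert (parts.end.values[:-1] == parts.start.values[1:]).all()
            assert (parts.feature_class == "exon").sum() == 3
            assert (parts.feature_class == "intron").sum() == 2

    def test_emitted_bed_passes_coordinate_sweep(self, tmp_path):
        g = e.generate_genome(5, 400_000, 0.41, seed=1)
        track = e.plant_annotation(g, seed=9)
        paths = track.to_bed_dir(tmp_path)
        lengths = g.lengths
        n = 0
        for cls, p in paths.items():  # independent reread of the emitted files
            for line in p.read_text().splitlines():
                chrom, s, ee, *_ = line.split("\t")
                s, ee = int(s), int(ee)
                assert 0 <= s < ee <= lengths[chrom], f"{cls} interval invalid"
                n += 1
        assert n == len(track)

    def test_capacity_error(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=1)
        cfg = {"gene": {"density": 500.0, "length": (10_000, 10_000)}}
        with pytest.raises(ValueError, match="capacity|cannot fit"):
            e.plant_annotation(g, cfg, seed=0)

    def test_gff_roundtrip(self, tmp_path):
        g = e.generate_genome(2, 100_000, 0.4, seed=1)
        track = e.plant_annotation(g, seed=4)
        track.to_gff3(tmp_path / "a.gff3")
        back = e.AnnotationTrack.from_gff3(tmp_path / "a.gff3")
        assert sorted(back.features) == sorted(track.features)


class TestSampleCircles:
    def test_forms_by_construction(self):
        g = e.generate_genome(3, 200_000, 0.4, seed=1)
        simple = e.sample_circles(g, 5, 0, seed=1)
        assert len(simple) == 5 and all(c.form == "simple" for c in simple)
        cplx = e.sample_circles(g, 0, 3, seed=2)
        assert len(cplx) == 3
        for c in cplx:
            assert len({f[0] for f in c.fragments}) >= 2

    def test_total_length_is_fragment_sum_and_in_range(self, nuclear_circles):
        for c in nuclear_circles:
            assert c.total_length == sum(fe - fs for _, fs, fe, _ in c.fragments)
            assert 300 <= c.total_length <= 8_000

    def test_mssi_flags_match_brute_force_scan(self):
        g = e.generate_genome(3, 200_000, 0.4, seed=3)
        circles = e.sample_circles(g, 20, 0, mssi_fraction=0.5, seed=4)
        n_flagged = sum(c.contains_mssi_site for c in circles)
        assert n_flagged >= 10  # the planted half, plus possible chance hits
        for c in circles:
            seq = e.circle_sequence(c, g)
            doubled = seq + seq[: len(MSSI_SITE) - 1]
            brute = any(
                doubled[i : i + len(MSSI_SITE)] == MSSI_SITE
                for i in range(len(seq))
            )
            assert c.contains_mssi_site == brute

    def test_size_range_validation(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=1)
        with pytest.raises(ValueError, match="size_range"):
            e.sample_circles(g, 1, 0, size_range=(50, 400))

    def test_mito_circle(self, study):
        _, circles = study
        mito = [c for c in circles if c.is_mito_like]
        assert len(mito) == 1
        assert mito[0].fragments == [("chrM_sim", 0, 16_500, "+")]

    def test_manifest_roundtrip(self, tmp_path, study):
        _, circles = study
        write_circle_manifest(circles, tmp_path / "truth.tsv")
        lines = (tmp_path / "truth.tsv").read_text().splitlines()
        assert len(lines) == len(circles) + 1  # header
        bed = (tmp_path / "truth.fragments.bed").read_text().splitlines()
        assert len(bed) == sum(len(c.fragments) for c in circles)


class TestSimulateReads:
    def test_concatemer_arithmetic_fixed_passes(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=1)
        circle = TruthCircle("c0", [("chr1", 5_000, 6_000, "+")])
        rs = e.simulate_reads(
            [circle], g, 20, ("fixed", 3), error_rates=(0, 0, 0), seed=5
        )
        by_read = {}
        for row in rs.paf_rows:
            by_read.setdefault(row[0], []).append(row)
        for r in rs.reads:
            assert len(r.sequence) == 3_000
            blocks = by_read[r.read_id]
            assert len(blocks) in (3, 4)  # 4 when the rotation splits a pass
            for row in blocks:
                assert row[5] == "chr1" and 5_000 <= row[7] < row[8] <= 6_000

    def test_linear_only(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=1)
        rs = e.simulate_reads([], g, 0, linear_read_count=100, seed=6)
        assert len(rs.reads) == 100
        assert len(rs.paf_rows) == 100  # one block each
        assert len({r[0] for r in rs.paf_rows}) == 100

    def test_empty_circles_with_reads_requested_is_error(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=1)
        with pytest.raises(ValueError, match="empty"):
            e.simulate_reads([], g, 5, seed=1)

    def test_substitution_rate_binomial(self):
        g = e.generate_genome(2, 100_000, 0.4, seed=2)
        circle = TruthCircle("c0", [("chr1", 10_000, 20_000, "+")])
        rs = e.simulate_reads(
            [circle], g, 1, ("fixed", 1), error_rates=(0.01, 0, 0),
            seed=8, both_strands=False,
        )
        read = rs.reads[0]
        rot = read.rotation_offset
        template = e.circle_sequence(circle, g)
        template = template[rot:] + template[:rot]
        mismatches = sum(a != b for a, b in zip(read.sequence, template))
        n, p = 10_000, 0.01
        sd = np.sqrt(n * p * (1 - p))
        assert abs(mismatches - n * p) <= 3 * sd

    def test_fastq_and_paf_consistent(self, clean_readset, tmp_path):
        ids_fastq = {r.read_id for r in clean_readset.reads}
        ids_paf = {row[0] for row in clean_readset.paf_rows}
        assert ids_paf == ids_fastq  # no ghosts in this set
        lens = {r.read_id: len(r.sequence) for r in clean_readset.reads}
        for row in clean_readset.paf_rows:
            assert row[1] == lens[row[0]]
            assert 0 <= row[2] < row[3] <= row[1]

    def test_truth_blocks_lie_inside_planted_fragments(self, clean_readset, nuclear_circles):
        frags = [(c, f) for c in nuclear_circles for f in c.fragments]
        for row in clean_readset.paf_rows:
            chrom, rs, re = row[5], row[7], row[8]
            assert any(
                chrom == fc and fs <= rs < re <= fe for _, (fc, fs, fe, _) in frags
            ), f"block {chrom}:{rs}-{re} outside every planted fragment"

    def test_byte_identical_for_fixed_seed(self, genome, nuclear_circles):
        a = e.simulate_reads(nuclear_circles, genome, 3, seed=17, linear_read_count=10)
        b = e.simulate_reads(nuclear_circles, genome, 3, seed=17, linear_read_count=10)
        assert [(r.read_id, r.sequence, r.quality) for r in a.reads] == [
            (r.read_id, r.sequence, r.quality) for r in b.reads
        ]
        assert a.paf_rows == b.paf_rows

    def test_ghost_reads_absent_from_paf(self, genome):
        rs = e.simulate_reads([], genome, 0, linear_read_count=20,
                              ghost_read_count=5, seed=3)
        assert len(rs.reads) == 25
        assert not any(row[0].startswith("ghost") for row in rs.paf_rows)

    def test_error_rate_validation(self, genome):
        with pytest.raises(ValueError, match="substitution"):
            e.simulate_reads([], genome, 0, linear_read_count=1,
                             error_rates=(0.5, 0, 0), seed=1)


class TestEnzymeModel:
    def _toy_circles(self):
        circles = [
            TruthCircle(f"c{i}", [("chr1", 100 * i, 100 * i + 50 + 250, "+")],
                        contains_mssi_site=(i < 4))
            for i in range(20)
        ]
        circles.append(TruthCircle("mito", [("chrM_sim", 0, 16_500, "+")], is_mito_like=True))
        return circles

    def test_mssi_removes_site_bearers_and_mito(self):
        survivors = e.apply_enzyme_model(self._toy_circles(), "mssi")
        assert len(survivors) == 16
        assert not any(c.contains_mssi_site or c.is_mito_like for c in survivors)

    def test_cas9_full_efficiency_removes_only_mito(self):
        survivors = e.apply_enzyme_model(self._toy_circles(), "cas9", 1.0, seed=1)
        assert len(survivors) == 20
        assert not any(c.is_mito_like for c in survivors)
        assert sum(c.contains_mssi_site for c in survivors) == 4

    def test_cas9_mito_survival_rate(self):
        circles = self._toy_circles()
        survived = sum(
            any(c.is_mito_like for c in e.apply_enzyme_model(circles, "cas9", 0.86, seed=s))
            for s in range(1_000)
        )
        frac = survived / 1_000
        se = np.sqrt(0.14 * 0.86 / 1_000)
        assert abs(frac - 0.14) <= 3 * se

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            e.apply_enzyme_model([], "exonuclease")
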