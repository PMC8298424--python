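"""Data model, format readers/writers, and interval arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rloopmap as rl
from rloopmap.core import FormatError, ars_position
from tests.conftest import random_intervals


# ---------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------

class TestBed:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert rl.read_bed(p) == []

    def test_single_line(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chrI\t100\t200\tp1\t0\t+\n")
        (iv,) = rl.read_bed(p)
        assert iv == rl.Interval("chrI", 100, 200, "+", "p1", 0.0)

    def test_round_trip_byte_identical(self, tmp_path):
        canonical = (
            "chrI\t100\t200\tp1\t0\t+\n"
            "chrI\t500\t900\tp2\t3.5\t-\n"
            "chrII\t0\t50\tp3\t0\t.\n"
        )
        src = tmp_path / "in.bed"
        src.write_text(canonical)
        dst = tmp_path / "out.bed"
        rl.write_bed(rl.read_bed(src), dst)
        assert dst.read_bytes() == src.read_bytes()

    @pytest.mark.parametrize("line", [
        "chrI\t100",  # too few columns
        "chrI\t200\t100\tx\t0\t+",  # start >= end
        "chrI\tx\t200",  # non-integer
        "chrI\t100\t200\tx\t0\t?",  # bad strand
    ])
    def test_malformed_rejected_with_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chrI\t0\t10\n" + line + "\n")
        with pytest.raises(FormatError, match=":2"):
            rl.read_bed(p)


# ---------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------

def _gff_row(chrom, start, end, strand, ftype="gene", name="g"):
    return (f"{chrom}\tsgd\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={name}\n")


class TestGff3:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\n" + _gff_row("chrI", 1, 10, "+"))
        (iv,) = rl.read_gff3_genes(p)
        assert (iv.start, iv.end) == (0, 10)
        assert iv.biotype == "gene"

    def test_headers_only(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text("##gff-version 3\n# comment\n")
        assert rl.read_gff3_genes(p) == []

    def test_three_gene_fixture_lengths(self, tmp_path):
        p = tmp_path / "c.gff3"
        p.write_text(
            "##gff-version 3\n"
            + _gff_row("chrI", 11, 20, "+", name="a")
            + _gff_row("chrI", 101, 350, "-", name="b")
            + _gff_row("chrII", 1, 1000, "+", name="c")
        )
        genes = rl.read_gff3_genes(p)
        assert [len(g) for g in genes] == [10, 250, 1000]
        # round trip through the writer preserves coordinates
        q = tmp_path / "rt.gff3"
        rl.write_gff3(genes, q)
        again = rl.read_gff3_genes(q)
        assert [(g.start, g.end, g.strand) for g in again] == \
            [(g.start, g.end, g.strand) for g in genes]

    def test_bad_coordinate_rejected(self, tmp_path):
        p = tmp_path / "d.gff3"
        p.write_text(_gff_row("chrI", 0, 10, "+"))
        with pytest.raises(FormatError):
            rl.read_gff3_genes(p)

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "e.gff3"
        p.write_text(_gff_row("chrI", 1, 10, "?"))
        with pytest.raises(FormatError):
            rl.read_gff3_genes(p)


# ---------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------

class TestBedgraph:
    def test_single_bin(self, tmp_path, small_genome):
        p = tmp_path / "a.bg"
        p.write_text("chrI\t0\t10\t5.0\n")
        t = rl.read_bedgraph(p, small_genome, 10)
        assert t.values("chrI")[0] == 5.0
        assert t.values("chrI")[1:].sum() == 0

    def test_empty_is_all_zero(self, tmp_path, small_genome):
        p = tmp_path / "b.bg"
        p.write_text("")
        t = rl.read_bedgraph(p, small_genome, 10)
        assert all(t.values(c).sum() == 0 for c in small_genome.chrom_names)

    def test_round_trip_preserves_nonzero_bins(self, tmp_path, small_genome):
        rng = np.random.default_rng(0)
        t = rl.CoverageTrack.zeros(small_genome, 10)
        for c in small_genome.chrom_names:
            v = t.values(c)
            idx = rng.choice(len(v), 40, replace=False)
            v[idx] = rng.integers(1, 50, 40)
        p = tmp_path / "c.bg"
        rl.write_bedgraph(t, p)
        t2 = rl.read_bedgraph(p, small_genome, 10)
        for c in small_genome.chrom_names:
            np.testing.assert_array_equal(t.values(c), t2.values(c))

    def test_off_grid_rejected(self, tmp_path, small_genome):
        p = tmp_path / "d.bg"
        p.write_text("chrI\t5\t15\t1.0\n")
        with pytest.raises(FormatError, match="bin grid"):
            rl.read_bedgraph(p, small_genome, 10)

    def test_unknown_chromosome_rejected(self, tmp_path, small_genome):
        p = tmp_path / "e.bg"
        p.write_text("chrX\t0\t10\t1.0\n")
        with pytest.raises(FormatError, match="unknown chromosome"):
            rl.read_bedgraph(p, small_genome, 10)


# ---------------------------------------------------------------------
# merge_and_fuse
# ---------------------------------------------------------------------

def brute_force_merge(intervals, fuse_dist, span=12_000):
    """Per-bp union, then close gaps strictly smaller than fuse_dist."""
    covered = np.zeros(span, bool)
    for iv in intervals:
        covered[iv.start:iv.end] = True
    runs = []
    i = 0
    while i < span:
        if covered[i]:
            j = i
            while j < span and covered[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    fused = [runs[0]] if runs else []
    for s, e in runs[1:]:
        if s - fused[-1][1] < fuse_dist:
            fused[-1][1] = e
        else:
            fused.append([s, e])
    return [(s, e) for s, e in fused]


class TestMergeAndFuse:
    def test_gap_below_threshold_fuses(self):
        out = rl.merge_and_fuse([rl.Interval("c", 100, 200),
                                 rl.Interval("c", 350, 500)], 200)
        assert [(o.start, o.end) for o in out] == [(100, 500)]

    def test_gap_exactly_threshold_stays(self):
        out = rl.merge_and_fuse([rl.Interval("c", 100, 200),
                                 rl.Interval("c", 400, 500)], 200)
        assert [(o.start, o.end) for o in out] == [(100, 200), (400, 500)]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_per_bp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, 200, max_pos=10_000, stranded=False)
        fuse = int(rng.integers(0, 400))
        out = rl.merge_and_fuse(ivs, fuse, stranded=False)
        assert [(o.start, o.end) for o in out] == \
            brute_force_merge(ivs, fuse)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_idempotent_and_spaced(self, seed):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, 50)
        out = rl.merge_and_fuse(ivs, 200)
        assert rl.merge_and_fuse(out, 200) == out
        by_key = {}
        for o in out:
            by_key.setdefault((o.chrom, o.strand), []).append(o)
        for group in by_key.values():
            for a, b in zip(group, group[1:]):
                assert b.start - a.end >= 200
        # coverage preserved: every input bp inside some output interval
        for iv in ivs:
            assert any(o.chrom == iv.chrom and o.start <= iv.start
                       and iv.end <= o.end for o in out
                       if o.strand in (iv.strand, "."))

    def test_stranded_runs_per_strand(self):
        ivs = [rl.Interval("c", 100, 200, "+"), rl.Interval("c", 250, 300, "-")]
        assert len(rl.merge_and_fuse(ivs, 200, stranded=True)) == 2
        assert len(rl.merge_and_fuse(ivs, 200, stranded=False)) == 1


# ---------------------------------------------------------------------
# overlaps
# ---------------------------------------------------------------------

class TestOverlaps:
    def test_half_open_boundary(self):
        assert not rl.overlaps(rl.Interval("c", 0, 10), rl.Interval("c", 10, 20))
        assert rl.overlaps(rl.Interval("c", 0, 10), rl.Interval("c", 9, 20))

    def test_different_chromosomes_false(self):
        assert not rl.overlaps(rl.Interval("c1", 0, 10),
                               rl.Interval("c2", 0, 10))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_batch_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, 50, chrom_names=("c1", "c2"))
        b = random_intervals(rng, 50, chrom_names=("c1", "c2"))
        expected = sorted(
            (i, j) for i in range(len(a)) for j in range(len(b))
            if rl.overlaps(a[i], b[j])
        )
        assert rl.overlap_pairs(a, b) == expected


def test_interval_validation():
    with pytest.raises(ValueError):
        rl.Interval("c", 10, 10)
    with pytest.raises(ValueError):
        rl.Interval("c", -1, 10)
    with pytest.raises(ValueError):
        rl.Interval("c", 0, 10, "x")


def test_genome_model_validation():
    with pytest.raises(ValueError):
        rl.GenomeModel(("a", "a"), (10, 10))
    with pytest.raises(ValueError):
        rl.GenomeModel(("a",), (0,))
    g = rl.GenomeModel(("a",), (95,))
    assert g.n_bins("a", 10) == 10
    with pytest.raises(ValueError):
        g.validate(rl.Interval("a", 90, 100))


def test_ars_position_single_bp_means_coordinate():
    assert ars_position(rl.Interval("c", 1400, 1401)) == 1400
    assert ars_position(rl.Interval("c", 100, 200)) == 150


def test_region_sum_pro_rata(small_genome):
    t = rl.CoverageTrack.zeros(small_genome, 10)
    t.values("chrI")[0:3] = [10.0, 20.0, 30.0]
    assert t.region_sum(rl.Interval("chrI", 0, 30)) == 60.0
    assert t.region_sum(rl.Interval("chrI", 5, 15)) == pytest.approx(15.0)
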