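"""Coverage normalization, oriented metaplots, asymmetry index."""

import numpy as np
import pytest

import rloopmap as rl
from rloopmap.core import CoverageTrack, GenomeModel, Interval
from rloopmap.simulate import expected_h2ap_mu


@pytest.fixture
def genome():
    return GenomeModel(("chrI",), (100_000,))


def _track(genome, fill=0.0, bin_width=10, **kw):
    t = CoverageTrack.zeros(genome, bin_width, **kw)
    for c in genome.chrom_names:
        t.data[c][:] = fill
    return t


class TestCoverageRpkm:
    def test_formula(self, genome):
        t = _track(genome, 1.0, total_reads=1e6)
        r = rl.coverage_rpkm(t)
        assert r.values("chrI")[0] == pytest.approx(100.0)
        assert r.normalization == "RPKM"

    def test_all_zero(self, genome):
        r = rl.coverage_rpkm(_track(genome, 0.0, total_reads=1e6))
        assert r.values("chrI").sum() == 0.0

    def test_conservation(self, genome):
        """Summing RPKM x bin_kb x reads_M recovers the counted reads."""
        rng = np.random.default_rng(0)
        t = _track(genome, 0.0)
        t.data["chrI"][:] = rng.poisson(5, t.data["chrI"].size)
        total = t.total()
        r = rl.coverage_rpkm(t, total_reads=total)
        back = r.values("chrI").sum() * (10 / 1000) * (total / 1e6)
        assert back == pytest.approx(total)

    def test_zero_total_rejected(self, genome):
        with pytest.raises(ValueError):
            rl.coverage_rpkm(_track(genome, 1.0), total_reads=0)


class TestScaleRnh:
    def test_identity_when_all_unique(self, genome):
        t = _track(genome, 3.0, total_reads=100, unique_reads=100)
        np.testing.assert_array_equal(rl.scale_rnh(t).values("chrI"),
                                      t.values("chrI"))

    def test_scale_factor(self, genome):
        t = _track(genome, 5.0, total_reads=1000, unique_reads=800)
        assert rl.scale_rnh(t).values("chrI")[0] == pytest.approx(4.0)

    def test_reciprocal_restores(self, genome):
        t = _track(genome, 7.0)
        s = rl.scale_rnh(t, unique_reads=800, total_reads=1000)
        np.testing.assert_allclose(s.values("chrI") * (1000 / 800),
                                   t.values("chrI"), atol=1e-12)

    def test_unique_cannot_exceed_total(self, genome):
        with pytest.raises(ValueError):
            rl.scale_rnh(_track(genome, 1.0), unique_reads=2000,
                         total_reads=1000)


class TestSubtractWt:
    def test_self_subtraction_zero(self, genome):
        t = _track(genome, 4.0)
        assert rl.subtract_wt(t, t).values("chrI").sum() == 0.0

    def test_zero_wt_identity_and_negatives_kept(self, genome):
        m = _track(genome, 1.0)
        w = _track(genome, 3.0)
        d = rl.subtract_wt(m, w)
        assert np.all(d.values("chrI") == -2.0)  # no clamping
        z = rl.subtract_wt(m, _track(genome, 0.0))
        np.testing.assert_array_equal(z.values("chrI"), m.values("chrI"))

    def test_region_mean_linearity(self, genome):
        rng = np.random.default_rng(1)
        m, w = _track(genome, 0.0), _track(genome, 0.0)
        m.data["chrI"][:] = rng.normal(10, 2, m.data["chrI"].size)
        w.data["chrI"][:] = rng.normal(4, 1, w.data["chrI"].size)
        d = rl.subtract_wt(m, w)
        iv = Interval("chrI", 1000, 4000)
        assert d.region_sum(iv) == pytest.approx(m.region_sum(iv)
                                                 - w.region_sum(iv))

    def test_bin_width_mismatch(self, genome):
        with pytest.raises(ValueError, match="bin widths"):
            rl.subtract_wt(_track(genome, 1.0),
                           _track(genome, 1.0, bin_width=20))


class TestReferencePoint:
    def test_constant_track_flat_profile(self, genome):
        t = _track(genome, 2.5)
        anchors = [Interval("chrI", 40_000, 41_000, "+")]
        mat = rl.metaplot_reference_point(t, anchors, 5000)
        prof = mat.mean_profile()
        assert prof.max() - prof.min() < 1e-9

    def test_delta_signal_peaks_at_center(self, genome):
        t = _track(genome, 0.0)
        t.data["chrI"][495:505] = 100.0  # hot 100 bp around bp 5000
        anchors = [Interval("chrI", 4500, 5500, "+")]
        mat = rl.metaplot_reference_point(t, anchors, 2000, n_bins=100)
        prof = mat.mean_profile()
        centre = len(prof) // 2
        assert abs(int(np.nanargmax(prof)) - centre) <= 1

    def test_edge_windows_nan_padded_or_dropped(self, genome):
        t = _track(genome, 1.0)
        partial = [Interval("chrI", 0, 100, "+")]  # window hangs off 5'
        mat = rl.metaplot_reference_point(t, partial, 5000)
        assert np.isnan(mat.values[0]).any()
        assert not np.isnan(mat.values[0]).all()

    def test_minus_anchor_row_reversed(self, genome):
        rng = np.random.default_rng(2)
        t = _track(genome, 0.0)
        t.data["chrI"][:] = rng.poisson(5, t.data["chrI"].size)
        plus = [Interval("chrI", 40_000, 41_000, "+")]
        minus = [Interval("chrI", 40_000, 41_000, "-")]
        mp = rl.metaplot_reference_point(t, plus, 3000, n_bins=300)
        mm = rl.metaplot_reference_point(t, minus, 3000, n_bins=300)
        np.testing.assert_array_equal(mm.values[0], mp.values[0][::-1])

    def test_replicate_average_equals_matrix_average(self, genome):
        rng = np.random.default_rng(3)
        t1, t2 = _track(genome, 0.0), _track(genome, 0.0)
        t1.data["chrI"][:] = rng.poisson(5, t1.data["chrI"].size)
        t2.data["chrI"][:] = rng.poisson(5, t2.data["chrI"].size)
        anchors = [Interval("chrI", s, s + 500, "+")
                   for s in (20_000, 50_000, 80_000)]
        joint = rl.metaplot_reference_point([t1, t2], anchors, 2000)
        m1 = rl.metaplot_reference_point(t1, anchors, 2000)
        m2 = rl.metaplot_reference_point(t2, anchors, 2000)
        np.testing.assert_allclose(joint.values,
                                   (m1.values + m2.values) / 2, atol=1e-12)


class TestScaledRegions:
    def test_constant_flat(self, genome):
        t = _track(genome, 3.0)
        mat = rl.metaplot_scaled_regions(t, [Interval("chrI", 40_000,
                                                      43_000, "+")])
        prof = mat.mean_profile()
        assert prof.max() - prof.min() < 1e-9

    def test_strand_reversal_exact(self, genome):
        rng = np.random.default_rng(4)
        t = _track(genome, 0.0)
        t.data["chrI"][:] = rng.poisson(8, t.data["chrI"].size)
        fwd = rl.metaplot_scaled_regions(t, [Interval("chrI", 40_000,
                                                      43_000, "+")])
        rev = rl.metaplot_scaled_regions(t, [Interval("chrI", 40_000,
                                                      43_000, "-")])
        np.testing.assert_array_equal(rev.values[0], fwd.values[0][::-1])

    def test_short_region_interpolates(self, genome):
        t = _track(genome, 2.0)
        mat = rl.metaplot_scaled_regions(t, [Interval("chrI", 40_000,
                                                      40_050, "+")],
                                         body_bins=100)
        assert mat.values.shape[0] == 1
        assert np.nanmax(mat.values) == pytest.approx(2.0)

    def test_sense_ramp_recovered(self, truth):
        """WT sense hybrid signal rises along the gene body (5'->3' ramp):
        mean of the last body tercile exceeds the first."""
        reps = [rl.simulate_drip_counts(truth, "WT", "S", r)
                for r in range(2)]
        genes = truth.genes
        sense, anti = rl.sense_antisense_split(
            rl.average_tracks([r.plus for r in reps]),
            rl.average_tracks([r.minus for r in reps]), genes)
        body = sense.values[:, (sense.positions >= 0)
                            & (sense.positions < 1)]
        prof = np.nanmean(body, axis=0)
        k = len(prof) // 3
        assert prof[-k:].mean() > prof[:k].mean()

    def test_sense_antisense_conservation(self, truth):
        """Sense + antisense matrices sum to the metaplot of the pooled
        (strand-summed) track."""
        s = rl.simulate_drip_counts(truth, "WT", "S", 0)
        genes = truth.genes[:40]
        sense, anti = rl.sense_antisense_split(s.plus, s.minus, genes)
        pooled = s.plus.copy()
        for c in pooled.data:
            pooled.data[c] = s.plus.data[c] + s.minus.data[c]
        both = rl.metaplot_scaled_regions(pooled, genes)
        np.testing.assert_allclose(sense.values + anti.values, both.values,
                                   atol=1e-9)

    def test_pure_plus_signal_splits_by_gene_strand(self, genome):
        plus = _track(genome, 5.0)
        minus = _track(genome, 0.0)
        gp = [Interval("chrI", 40_000, 42_000, "+")]
        gm = [Interval("chrI", 40_000, 42_000, "-")]
        s1, a1 = rl.sense_antisense_split(plus, minus, gp)
        assert np.nansum(s1.values) > 0 and np.nansum(a1.values) == 0
        s2, a2 = rl.sense_antisense_split(plus, minus, gm)
        assert np.nansum(s2.values) == 0 and np.nansum(a2.values) > 0


class TestAsymmetryIndex:
    def _matrix(self, rows, flank=5000, anchors=None):
        rows = np.asarray(rows, dtype=float)
        n = rows.shape[1]
        step = 2 * flank / n
        pos = -flank + step * (np.arange(n) + 0.5)
        anchors = anchors or [Interval("c", 0, 1000, "+")] * rows.shape[0]
        return rl.MetaplotMatrix(rows, pos, anchors, "refpoint")

    def test_all_downstream_gives_one(self):
        row = np.zeros(100)
        row[80:] = 5.0
        ai = rl.asymmetry_index(self._matrix([row]), core_exclusion_bp=1000)
        assert ai.mean == pytest.approx(1.0)

    def test_symmetric_gives_zero(self):
        row = np.zeros(100)
        row[10:20] = 3.0
        row[80:90] = 3.0
        ai = rl.asymmetry_index(self._matrix([row]), core_exclusion_bp=1000)
        assert ai.mean == pytest.approx(0.0, abs=1e-12)

    def test_no_flank_signal_excluded(self):
        ai = rl.asymmetry_index(self._matrix([np.zeros(100)]),
                                core_exclusion_bp=1000)
        assert ai.n_excluded == 1 and ai.ai.size == 0

    def test_planted_asymmetry_recovered(self, truth):
        """a_dam = 0.8 halos around planted anchors, fork-oriented:
        mean AI within 0.1 of (0.8-0.2)/(0.8+0.2) = 0.6."""
        track, wt = rl.simulate_h2ap_track(truth, "sen1", 1)
        delta = rl.subtract_wt(track, wt)
        anchors, a = truth.damage_anchors("sen1")
        assert a == truth.config.a_dam
        mat = rl.metaplot_reference_point(
            delta, anchors, 5000, orient_by="fork-direction",
            ars_midpoints=truth.ars_midpoints)
        ai = rl.asymmetry_index(mat, seed=1)
        assert abs(ai.mean - 0.6) < 0.1

    def test_symmetric_damage_near_zero(self, truth):
        track, wt = rl.simulate_h2ap_track(truth, "hpr1", 1)
        delta = rl.subtract_wt(track, wt)
        anchors, a = truth.damage_anchors("hpr1")
        assert a == 0.5
        mat = rl.metaplot_reference_point(
            delta, anchors, 5000, orient_by="fork-direction",
            ars_midpoints=truth.ars_midpoints)
        ai = rl.asymmetry_index(mat, seed=1)
        assert abs(ai.mean) < 0.05

    def test_fork_downstream_bias_one_sided(self, truth):
        """Mean downstream-half signal exceeds upstream for the planted
        asymmetric condition (bootstrap on the AI mean, p < 0.01)."""
        track, wt = rl.simulate_h2ap_track(truth, "sen1", 2)
        delta = rl.subtract_wt(track, wt)
        anchors, _ = truth.damage_anchors("sen1")
        mat = rl.metaplot_reference_point(
            delta, anchors, 5000, orient_by="fork-direction",
            ars_midpoints=truth.ars_midpoints)
        ai = rl.asymmetry_index(mat, n_boot=1000, seed=2)
        assert ai.ci_low > 0  # 95% CI strictly positive


def test_mirror_equivariance(genome):
    """Reversing the genome (coordinates, array order, strands, origin
    positions) leaves fork-oriented reference-point profiles unchanged.

    Anchors sit on even coordinates and windows sample bin centres, so
    the symmetry is exact (no bin-boundary discretization jitter).
    """
    L = 100_000
    rng = np.random.default_rng(6)
    track = CoverageTrack.zeros(genome, 10)
    track.data["chrI"][:] = rng.poisson(4, L // 10).astype(float)
    track.data["chrI"][3000:3100] += 30.0  # asymmetric blob near bp 30500

    anchors = [Interval("chrI", 28_000, 30_000, "+"),
               Interval("chrI", 61_000, 63_000, "-"),
               Interval("chrI", 44_200, 45_000, "+")]
    ars = [Interval("chrI", 20_000, 20_001), Interval("chrI", 70_000, 70_001)]
    mat = rl.metaplot_reference_point(track, anchors, 5000, n_bins=1000,
                                      orient_by="fork-direction",
                                      ars_midpoints=ars)

    mirrored = track.copy()
    mirrored.data["chrI"] = mirrored.data["chrI"][::-1].copy()

    def flip(iv):
        strand = {"+": "-", "-": "+", ".": "."}[iv.strand]
        return Interval(iv.chrom, L - iv.end, L - iv.start, strand)

    mat2 = rl.metaplot_reference_point(mirrored, [flip(a) for a in anchors],
                                       5000, n_bins=1000,
                                       orient_by="fork-direction",
                                       ars_midpoints=[flip(a) for a in ars])
    np.testing.assert_allclose(mat.values, mat2.values, atol=1e-12)
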