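"""Coverage normalization and oriented average-signal profiles.

RPKM coverage (bin 10 by default), RNase-H scale correction
(unique/total mapped reads), WT subtraction (never clamped — regions
where WT exceeds the mutant stay negative), reference-point and
scaled-region metaplots oriented 5'->3' or by replication-fork direction,
a sense/antisense split for stranded hybrid maps, and an asymmetry index
AI = (D - U)/(D + U) over the flank means around each anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import CoverageTrack, Interval, average_tracks

log = logging.getLogger(__name__)


def coverage_rpkm(track: CoverageTrack, total_reads: float | None = None) -> CoverageTrack:
    """RPKM-normalize a raw count track: count / (bin_kb * reads_M)."""
    total = track.total_reads if total_reads is None else total_reads
    if not total or total <= 0:
        raise ValueError("total_reads must be positive for RPKM")
    denom = (track.bin_width / 1000.0) * (total / 1e6)
    out = track.copy(normalization="RPKM")
    for c in out.data:
        out.data[c] = track.data[c] / denom
    out.total_reads = total
    return out


def scale_rnh(track: CoverageTrack, unique_reads: float | None = None,
              total_reads: float | None = None) -> CoverageTrack:
    """Scale an RNase-H-treated sample by unique/total mapped reads so it
    is comparable with untreated samples."""
    unique = track.unique_reads if unique_reads is None else unique_reads
    total = track.total_reads if total_reads is None else total_reads
    if unique is None or total is None or total <= 0 or unique <= 0:
        raise ValueError("unique and total read counts required")
    if unique > total:
        raise ValueError("unique_reads cannot exceed total_reads")
    out = track.copy(normalization="RNH-scaled")
    f = unique / total
    for c in out.data:
        out.data[c] = track.data[c] * f
    return out


def subtract_wt(mutant: CoverageTrack, wt: CoverageTrack) -> CoverageTrack:
    """Elementwise mutant - WT; negative values are preserved."""
    if mutant.bin_width != wt.bin_width:
        raise ValueError("bin widths differ")
    if mutant.genome != wt.genome:
        raise ValueError("genomes differ")
    out = mutant.copy(normalization="WT-subtracted")
    for c in out.data:
        out.data[c] = mutant.data[c] - wt.data[c]
    return out


@dataclass
class MetaplotMatrix:
    """Anchors x positions oriented signal matrix.

    ``positions`` are bp offsets from the anchor midpoint (reference-
    point mode) or scaled-axis coordinates (scaled mode).  Rows are
    flipped so the axis runs 5'->3' (or fork-upstream -> fork-downstream).
    NaN marks positions falling outside the chromosome.
    """

    values: np.ndarray
    positions: np.ndarray
    anchors: list
    kind: str  # "refpoint" | "scaled"
    n_dropped: int = 0

    def mean_profile(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


def _as_track(tracks) -> CoverageTrack:
    if isinstance(tracks, CoverageTrack):
        return tracks
    return average_tracks(list(tracks))


def _lookup(track: CoverageTrack, chrom: str, bp: np.ndarray) -> np.ndarray:
    """Track values at (possibly fractional) bp positions; NaN outside."""
    clen = track.genome.length(chrom)
    v = track.data[chrom]
    out = np.full(bp.shape, np.nan)
    ok = (bp >= 0) & (bp < clen)
    idx = np.minimum((bp[ok] // track.bin_width).astype(int), len(v) - 1)
    out[ok] = v[idx]
    return out


def _fork_direction(iv: Interval, ars_midpoints) -> str:
    from .simulate import _nearest_ars_direction

    return _nearest_ars_direction(iv.midpoint, iv.chrom, ars_midpoints)


def metaplot_reference_point(tracks, anchors: list, flank_bp: int = 5000,
                             n_bins: int | None = None,
                             orient_by: str | None = "anchor-strand",
                             ars_midpoints: list | None = None) -> MetaplotMatrix:
    """Signal in a fixed window (anchor midpoint +/- flank) per anchor.

    ``orient_by``: "anchor-strand" flips rows of minus-strand anchors;
    "fork-direction" flips rows of anchors left of their nearest origin
    midpoint (requires ``ars_midpoints``), so the axis always runs
    fork-upstream -> fork-downstream; None keeps genomic orientation.
    Replicate track lists are averaged before plotting.  Anchors whose
    window lies entirely off the chromosome are dropped (logged).
    """
    track = _as_track(tracks)
    if n_bins is None:
        n_bins = max(int(2 * flank_bp // track.bin_width), 2)
    step = 2.0 * flank_bp / n_bins
    offsets = -flank_bp + step * (np.arange(n_bins) + 0.5)
    rows, kept = [], []
    dropped = 0
    for iv in anchors:
        iv = iv.interval if hasattr(iv, "interval") else iv
        row = _lookup(track, iv.chrom, iv.midpoint + offsets)
        if np.all(np.isnan(row)):
            dropped += 1
            continue
        if orient_by == "anchor-strand":
            flip = iv.strand == "-"
        elif orient_by == "fork-direction":
            if ars_midpoints is None:
                raise ValueError("fork orientation requires ars_midpoints")
            flip = _fork_direction(iv, ars_midpoints) == "-"
        elif orient_by is None:
            flip = False
        else:
            raise ValueError(f"unknown orient_by {orient_by!r}")
        rows.append(row[::-1] if flip else row)
        kept.append(iv)
    if dropped:
        log.info("dropped %d anchors with fully off-chromosome windows",
                 dropped)
    values = np.array(rows) if rows else np.empty((0, n_bins))
    return MetaplotMatrix(values, offsets, kept, "refpoint", dropped)


def metaplot_scaled_regions(tracks, regions: list, body_bins: int = 100,
                            flank_bp: int = 2000,
                            flank_bin: int = 10) -> MetaplotMatrix:
    """Gene-body-style profile: flanks at fixed resolution, body linearly
    rescaled to ``body_bins``.  Minus-strand regions are reversed so the
    axis runs 5'->3'.  Positions: negative = upstream flank (bp), [0, 1)
    = scaled body, >= 1 = downstream flank offset in units of body."""
    track = _as_track(tracks)
    n_f = max(flank_bp // flank_bin, 1)
    up_off = -flank_bp + flank_bin * (np.arange(n_f) + 0.5)
    body_frac = (np.arange(body_bins) + 0.5) / body_bins
    down_off = flank_bin * (np.arange(n_f) + 0.5)
    positions = np.concatenate([
        up_off / flank_bp,  # [-1, 0)
        body_frac,  # [0, 1)
        1.0 + down_off / flank_bp,  # [1, 2)
    ])
    rows, kept = [], []
    dropped = 0
    for iv in regions:
        iv = iv.interval if hasattr(iv, "interval") else iv
        body_bp = iv.start + body_frac * len(iv)
        bp = np.concatenate([iv.start + up_off, body_bp, iv.end + down_off])
        row = _lookup(track, iv.chrom, bp)
        if np.all(np.isnan(row)):
            dropped += 1
            continue
        rows.append(row[::-1] if iv.strand == "-" else row)
        kept.append(iv)
    values = np.array(rows) if rows else np.empty((0, positions.size))
    return MetaplotMatrix(values, positions, kept, "scaled", dropped)


def sense_antisense_split(plus_track, minus_track, genes: list,
                          **kwargs) -> tuple:
    """Split stranded signal over genes into sense (matching the gene's
    strand) and antisense matrices, both oriented 5'->3' of the gene."""
    if plus_track is None or minus_track is None:
        raise ValueError("both strand tracks are required")
    mat_p = metaplot_scaled_regions(plus_track, genes, **kwargs)
    mat_m = metaplot_scaled_regions(minus_track, genes, **kwargs)
    if len(mat_p.anchors) != len(mat_m.anchors):
        raise ValueError("strand tracks disagree on droppable anchors")
    sense_rows, anti_rows = [], []
    for i, g in enumerate(mat_p.anchors):
        if g.strand == "-":
            sense_rows.append(mat_m.values[i])
            anti_rows.append(mat_p.values[i])
        else:
            sense_rows.append(mat_p.values[i])
            anti_rows.append(mat_m.values[i])
    sense = MetaplotMatrix(np.array(sense_rows), mat_p.positions,
                           mat_p.anchors, "scaled", mat_p.n_dropped)
    anti = MetaplotMatrix(np.array(anti_rows), mat_p.positions,
                          mat_p.anchors, "scaled", mat_p.n_dropped)
    return sense, anti


@dataclass
class AsymmetryIndex:
    """Per-anchor AI = (D - U)/(D + U) over flank means, with a bootstrap
    CI on the mean.  AI is 0 for symmetric spreading, positive when the
    signal mass sits downstream of the anchor orientation."""

    ai: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_excluded: int


def asymmetry_index(matrix: MetaplotMatrix, core_exclusion_bp: float | None = None,
                    n_boot: int = 1000, seed: int = 0) -> AsymmetryIndex:
    """Asymmetry of signal around reference-point anchors.

    Upstream/downstream flank means exclude ``core_exclusion_bp`` around
    the anchor midpoint; by default each anchor excludes its own body
    (half its length on each side), so AI measures spreading, not the
    peak itself.  Mean signals are floored at 0 (WT-subtracted input can
    dip negative); anchors with D + U = 0 are excluded and counted.
    """
    if matrix.kind != "refpoint":
        raise ValueError("asymmetry index needs a reference-point matrix")
    pos = matrix.positions
    ais = []
    excluded = 0
    for i, iv in enumerate(matrix.anchors):
        core = (len(iv) / 2.0 if core_exclusion_bp is None
                else float(core_exclusion_bp))
        row = matrix.values[i]
        u = row[pos < -core]
        d = row[pos > core]
        if u.size == 0 or d.size == 0:
            raise ValueError("core exclusion leaves no flank positions")
        U = max(float(np.nanmean(u)), 0.0) if not np.all(np.isnan(u)) else np.nan
        D = max(float(np.nanmean(d)), 0.0) if not np.all(np.isnan(d)) else np.nan
        if not np.isfinite(U) or not np.isfinite(D) or (U + D) <= 0:
            excluded += 1
            continue
        ais.append((D - U) / (D + U))
    if excluded:
        log.info("asymmetry index: excluded %d anchors with no flank signal",
                 excluded)
    ais = np.array(ais)
    if ais.size == 0:
        return AsymmetryIndex(ais, float("nan"), float("nan"), float("nan"),
                              excluded)
    rng = np.random.default_rng(seed)
    boots = np.array([
        rng.choice(ais, size=ais.size, replace=True).mean()
        for _ in range(n_boot)
    ])
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return AsymmetryIndex(ais, float(ais.mean()), float(lo), float(hi),
                          excluded)
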