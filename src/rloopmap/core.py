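"""Genomic data model: genomes, strand-aware intervals, binned coverage.

Everything downstream (peak calling, differential testing, metaprofiles,
conflict analysis) speaks in these types.  Coordinates are 0-based,
half-open everywhere; GFF3 input is converted on read.  Coverage is stored
dense per chromosome, which is cheap at yeast scale and removes any
resampling ambiguity: tracks live on a fixed bin grid and inputs that do
not align to it are rejected, never repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: normalization tags a CoverageTrack may carry
NORMALIZATIONS = ("raw", "RPKM", "WT-subtracted", "RNH-scaled")


class FormatError(ValueError):
    """A file violated its format contract (bad coordinates, bad grid...)."""


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths; the coordinate frame for
    every interval and track."""

    chrom_names: tuple
    chrom_lengths: tuple
    bin_width: int | None = None

    def __post_init__(self):
        names = tuple(self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        if len(names) != len(lengths):
            raise ValueError("names and lengths differ in length")
        if any(l <= 0 for l in lengths):
            raise ValueError("chromosome lengths must be positive")

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return -(-self.length(chrom) // bin_width)  # ceil division

    def validate(self, iv: "Interval") -> None:
        if iv.chrom not in self:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self.length(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.length(iv.chrom)}"
            )

    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))


@dataclass(frozen=True)
class Interval:
    """Strand-aware genomic span, 0-based half-open.

    ``biotype`` carries the feature class for annotation features read
    from GFF3 (``gene``, ``tRNA_gene``, ...); it is None for plain spans.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    biotype: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.strand)


def ars_position(iv: Interval) -> float:
    """Coordinate of an origin midpoint given as an interval: a 1-bp BED
    interval [m, m+1) means position m; wider intervals use their centre."""
    return float(iv.start) if len(iv) == 1 else iv.midpoint


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two intervals share at least one bp (strand ignored;
    different chromosomes simply do not overlap)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_pairs(a: Sequence[Interval], b: Sequence[Interval]) -> list:
    """All (i, j) index pairs with a[i] overlapping b[j].

    Sorted sweep per chromosome; output ordered by (i, j).
    """
    by_chrom: dict = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom.values():
        lst.sort()
    out = []
    for i, iv in enumerate(a):
        lst = by_chrom.get(iv.chrom)
        if not lst:
            continue
        starts = [x[0] for x in lst]
        # candidates: those with start < iv.end; filter by end > iv.start
        import bisect

        hi = bisect.bisect_left(starts, iv.end)
        for start, end, j in lst[:hi]:
            if end > iv.start:
                out.append((i, j))
    out.sort()
    return out


def merge_and_fuse(
    intervals: Iterable[Interval], fuse_dist: int = 200, stranded: bool = True
) -> list:
    """Union of intervals, additionally fusing neighbours separated by a
    gap strictly smaller than ``fuse_dist`` ("closer than" is strict).

    With ``stranded=True`` the operation runs independently per strand
    (stranded hybrid maps); otherwise strand is ignored and the output
    carries strand ".".  Output is sorted, non-overlapping, and any two
    output intervals on the same (chrom, strand) are >= fuse_dist apart.
    """
    if fuse_dist < 0:
        raise ValueError("fuse_dist must be >= 0")
    groups: dict = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand if stranded else ".")
        groups.setdefault(key, []).append(iv)
    out = []
    for (chrom, strand), ivs in groups.items():
        ivs.sort(key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end < fuse_dist:  # overlap or small gap
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end, strand))
    out.sort(key=Interval.sort_key)
    return out


@dataclass
class CoverageTrack:
    """Fixed-bin-width signal, dense per chromosome.

    ``data[chrom]`` has length ceil(chrom_length / bin_width).  ``strand``
    is "." for unstranded assays (ChIP) and +/- for stranded hybrid maps.
    ``total_reads``/``unique_reads`` feed RPKM and RNH scaling.
    """

    genome: GenomeModel
    bin_width: int
    data: dict
    strand: str = "."
    normalization: str = "raw"
    total_reads: float | None = None
    unique_reads: float | None = None

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for chrom in self.genome.chrom_names:
            n = self.genome.n_bins(chrom, self.bin_width)
            arr = np.asarray(self.data.get(chrom, np.zeros(n)), dtype=float)
            if arr.shape != (n,):
                raise ValueError(
                    f"track for {chrom} has {arr.shape[0]} bins, expected {n}"
                )
            self.data[chrom] = arr

    @classmethod
    def zeros(cls, genome: GenomeModel, bin_width: int, **kw) -> "CoverageTrack":
        data = {
            c: np.zeros(genome.n_bins(c, bin_width)) for c in genome.chrom_names
        }
        return cls(genome, bin_width, data, **kw)

    def values(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def copy(self, **changes) -> "CoverageTrack":
        new = CoverageTrack(
            genome=self.genome,
            bin_width=self.bin_width,
            data={c: v.copy() for c, v in self.data.items()},
            strand=self.strand,
            normalization=self.normalization,
            total_reads=self.total_reads,
            unique_reads=self.unique_reads,
        )
        for k, v in changes.items():
            setattr(new, k, v)
        return new

    def region_sum(self, iv: Interval) -> float:
        """Sum of signal over the interval; partial bins contribute
        pro-rata by overlapped fraction."""
        self.genome.validate(iv)
        bw = self.bin_width
        v = self.data[iv.chrom]
        b0, b1 = iv.start // bw, -(-iv.end // bw)
        total = 0.0
        for b in range(b0, b1):
            lo = max(iv.start, b * bw)
            hi = min(iv.end, (b + 1) * bw, self.genome.length(iv.chrom))
            if hi > lo:
                total += v[b] * (hi - lo) / bw
        return total

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


def average_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Elementwise mean of replicate tracks (used before metaplotting)."""
    first = tracks[0]
    for t in tracks[1:]:
        if t.bin_width != first.bin_width or t.genome != first.genome:
            raise ValueError("tracks must share genome and bin width")
    out = first.copy()
    for chrom in first.genome.chrom_names:
        out.data[chrom] = np.mean([t.data[chrom] for t in tracks], axis=0)
    out.total_reads = float(
        np.mean([t.total_reads for t in tracks])
    ) if all(t.total_reads is not None for t in tracks) else None
    return out


@dataclass
class BinnedCounts:
    """Regions x samples integer count matrix with library sizes."""

    regions: list
    samples: list
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape must be (n_regions, n_samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.library_sizes.shape != (len(self.samples),):
            raise ValueError("one library size per sample required")

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)
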