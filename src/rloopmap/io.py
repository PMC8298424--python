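"""Readers and writers for the interchange formats (BED6, GFF3, bedGraph).

These are deliberately strict: coordinate violations and off-grid
bedGraph intervals raise :class:`~rloopmap.core.FormatError` with the
offending line number rather than being silently repaired — downstream
statistics should never see quietly mangled coordinates.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .core import CoverageTrack, FormatError, GenomeModel, Interval, STRANDS


def read_bed(path) -> list:
    """Read a BED3/BED6 file into intervals (0-based half-open, as BED).

    Missing strand becomes "."; columns beyond 6 are ignored.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid span {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad score") from None
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            out.append(Interval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    """Write 6-column BED (name "." if unset, score 0 if unset)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def read_gff3_genes(path, feature_types=None) -> list:
    """Read feature rows from GFF3 into intervals.

    GFF3 is 1-based inclusive; coordinates are converted to 0-based
    half-open (start-1, end).  The feature type column becomes the
    interval's ``biotype``; the name is taken from the ``ID=`` or
    ``Name=`` attribute when present.  ``feature_types`` restricts which
    type values are kept (None keeps every feature row).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 columns")
            chrom, _, ftype, start_s, end_s, score_s, strand, _, attrs = fields[:9]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise FormatError(
                    f"{path}:{lineno}: invalid 1-based span {start}-{end}"
                )
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            name = None
            for key in ("ID", "Name", "gene"):
                for part in attrs.split(";"):
                    if part.startswith(key + "="):
                        name = part[len(key) + 1 :]
                        break
                if name:
                    break
            score = None if score_s in (".", "") else float(score_s)
            out.append(
                Interval(chrom, start - 1, end, strand, name, score, biotype=ftype)
            )
    return out


def write_gff3(intervals: Iterable[Interval], path, source="rloopmap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, iv in enumerate(intervals):
            attrs = f"ID={iv.name or f'feature{i}'}"
            fh.write(
                f"{iv.chrom}\t{source}\t{iv.biotype or 'gene'}\t"
                f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def read_bedgraph(path, genome: GenomeModel, bin_width: int, **track_kw) -> CoverageTrack:
    """Read a bedGraph onto the track's bin grid.

    Every interval must start and end on a multiple of ``bin_width``
    (a final interval may end at the chromosome length).  Off-grid
    intervals or unknown chromosomes are errors; uncovered bins are 0.
    """
    track = CoverageTrack.zeros(genome, bin_width, **track_kw)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: fewer than 4 columns")
            chrom = fields[0]
            if chrom not in genome:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed row") from None
            clen = genome.length(chrom)
            if start < 0 or start >= end or end > clen:
                raise FormatError(f"{path}:{lineno}: invalid span {start}-{end}")
            if start % bin_width != 0 or (end % bin_width != 0 and end != clen):
                raise FormatError(
                    f"{path}:{lineno}: interval {start}-{end} is off the "
                    f"{bin_width} bp bin grid"
                )
            track.data[chrom][start // bin_width : -(-end // bin_width)] = value
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write nonzero bins as bedGraph, merging runs of equal value."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.genome.chrom_names:
            v = track.data[chrom]
            clen = track.genome.length(chrom)
            i = 0
            n = len(v)
            while i < n:
                if v[i] == 0:
                    i += 1
                    continue
                j = i
                while j + 1 < n and v[j + 1] == v[i]:
                    j += 1
                start, end = i * bw, min((j + 1) * bw, clen)
                val = v[i]
                if float(val).is_integer():
                    val = int(val)
                fh.write(f"{chrom}\t{start}\t{end}\t{val}\n")
                i = j + 1
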