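"""Transcription-replication conflict orientation analysis.

Forks move bidirectionally from each early origin (ARS) midpoint.  A
protein-coding gene within 1 kb of a midpoint is codirectional (CD) when
its transcription runs with the incoming fork and head-on (HO) when it
opposes it.  Gain percentages per orientation are compared with a 2x2
chi-square (1 df, no continuity correction); the one-sided p-value halves
the two-sided tail when the observed direction matches the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .core import Interval, ars_position, overlap_pairs


@dataclass(frozen=True)
class OrientationCall:
    gene: Interval
    ars: Interval
    distance: float  # bp from ARS midpoint to nearest gene edge, 0 inside
    side: str  # "left" | "right" of the ARS midpoint
    fork_direction: str  # "+" rightward, "-" leftward
    orientation: str  # "HO" | "CD"


def _gene_ars_distance(gene: Interval, ars_mid: float) -> float:
    if gene.start <= ars_mid < gene.end:
        return 0.0
    return gene.start - ars_mid if ars_mid < gene.start else ars_mid - gene.end


def ars_proximal_genes(genes: list, ars_midpoints: list,
                       max_dist: int = 1000) -> list:
    """Genes strictly closer than ``max_dist`` bp (nearest edge, 0 if the
    midpoint falls inside the gene) to their nearest origin midpoint.

    Returns (gene, nearest ARS, distance) triples; ties broken by the
    lower-coordinate origin.  Ambiguously placed genes (midpoint exactly
    on the origin midpoint) are excluded by :func:`orient_ho_cd` later.
    """
    if not ars_midpoints:
        raise ValueError("empty ARS set")
    out = []
    for g in genes:
        best = None
        for a in sorted(ars_midpoints, key=Interval.sort_key):
            if a.chrom != g.chrom:
                continue
            d = _gene_ars_distance(g, ars_position(a))
            if best is None or d < best[1]:
                best = (a, d)
        if best is not None and best[1] < max_dist:
            out.append((g, best[0], best[1]))
    return out


def orient_ho_cd(gene: Interval, ars_midpoint: float) -> str | None:
    """HO/CD orientation of a gene relative to the fork from an origin.

    The gene's side is the sign of (gene midpoint - ARS midpoint); the
    fork on that side moves away from the origin.  CD iff the gene's
    strand equals the fork direction.  Returns None when the gene
    midpoint sits exactly on the origin midpoint (ambiguous).
    """
    delta = gene.midpoint - ars_midpoint
    if delta == 0:
        return None
    fork = "+" if delta > 0 else "-"
    return "CD" if gene.strand == fork else "HO"


def orientation_calls(genes: list, ars_midpoints: list,
                      max_dist: int = 1000) -> list:
    """Full orientation table for ARS-proximal genes; ambiguous genes are
    dropped (every other gene gets exactly one HO/CD label)."""
    out = []
    for g, a, d in ars_proximal_genes(genes, ars_midpoints, max_dist):
        orient = orient_ho_cd(g, ars_position(a))
        if orient is None:
            continue
        side = "right" if g.midpoint > ars_position(a) else "left"
        fork = "+" if side == "right" else "-"
        out.append(OrientationCall(g, a, d, side, fork, orient))
    return out


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] for (HO, CD) x (gain, no-gain)."""

    table: np.ndarray
    row_labels: tuple = ("HO", "CD")
    col_labels: tuple = ("gain", "no-gain")

    @property
    def percentages(self) -> dict:
        out = {}
        for i, lab in enumerate(self.row_labels):
            total = self.table[i].sum()
            out[lab] = float("nan") if total == 0 else \
                100.0 * self.table[i, 0] / total
        return out


def orientation_gain_table(calls: list, gain_regions: list) -> ContingencyTable2x2:
    """Cross orientation (HO/CD) with gain status: a gene gains iff it
    overlaps at least one gain region (>= 1 bp)."""
    genes = [c.gene for c in calls]
    ivs = [r.interval if hasattr(r, "interval") else r for r in gain_regions]
    hit = {i for i, _ in overlap_pairs(genes, ivs)}
    t = np.zeros((2, 2), dtype=int)
    for i, c in enumerate(calls):
        row = 0 if c.orientation == "HO" else 1
        col = 0 if i in hit else 1
        t[row, col] += 1
    return ContingencyTable2x2(t)


def chi_square_2x2(table, alternative: str = "greater"):
    """2x2 chi-square without continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), 1 df.  The one-sided
    p halves the two-sided tail when the observed association direction
    (row-0 gain fraction vs row-1) matches ``alternative`` ("greater":
    row 0 has the higher gain fraction; "less": lower), else 1 - half.
    ``alternative="two-sided"`` returns the plain upper-tail p.
    """
    t = np.asarray(table.table if hasattr(table, "table") else table,
                   dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    a, b, c, d = t.ravel()
    n = t.sum()
    margins = np.array([a + b, c + d, a + c, b + d])
    if np.any(margins == 0):
        raise ValueError("degenerate table: a margin is zero")
    stat = float(n * (a * d - b * c) ** 2 / margins.prod())
    p_two = float(chi2.sf(stat, df=1))
    if alternative == "two-sided":
        return stat, p_two
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    # observed direction: does row 0 show the larger gain fraction?
    f0 = a / (a + b)
    f1 = c / (c + d)
    observed_greater = f0 > f1
    if stat == 0.0 or f0 == f1:
        return stat, 0.5
    matches = observed_greater == (alternative == "greater")
    return stat, p_two / 2.0 if matches else 1.0 - p_two / 2.0
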