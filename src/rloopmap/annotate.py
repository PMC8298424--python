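"""Peak-to-feature annotation and gain-gene property comparisons.

A peak annotates to a feature when it overlaps it or lies within 200 bp
upstream of the feature's 5' end (strand-relative, strict "closer than");
one peak may annotate to several features.  Peaks matching nothing are
reported explicitly as unannotated so class fractions have a denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ranksums

from .core import Interval, overlaps

#: biotype -> reported feature class
_CLASS_MAP = {
    "gene": "protein-coding",
    "mRNA": "protein-coding",
    "protein_coding": "protein-coding",
    "tRNA_gene": "tRNA",
    "tRNA": "tRNA",
    "snoRNA_gene": "snoRNA",
    "snoRNA": "snoRNA",
    "telomere": "telomere",
}


def feature_class(feature: Interval) -> str:
    return _CLASS_MAP.get(feature.biotype or "", "other")


@dataclass(frozen=True)
class PeakAnnotation:
    peak_index: int
    feature_index: int | None  # None => unannotated
    feature_class: str
    relation: str  # "overlap" | "upstream" | "unannotated"


def _upstream_window(feature: Interval, upstream_max: int) -> Interval | None:
    """Promoter-side window (TSS - upstream_max, TSS], half-open in
    0-based coordinates, on the feature's strand."""
    if feature.strand == "-":
        start, end = feature.end, feature.end + upstream_max
    else:  # '+' or unstranded features treat start as the 5' end
        start, end = feature.start - upstream_max, feature.start
    if end <= max(start, 0):
        return None
    return Interval(feature.chrom, max(start, 0), end, feature.strand)


def annotate_peaks(peaks: list, features: list,
                   upstream_max: int = 200) -> list:
    """Annotate each peak to every feature it overlaps or sits closer
    than ``upstream_max`` bp upstream of.  Unmatched peaks yield a single
    "unannotated" record, so every peak appears at least once."""
    ivs = [p.interval if hasattr(p, "interval") else p for p in peaks]
    out = []
    for i, pk in enumerate(ivs):
        hit = False
        for j, ft in enumerate(features):
            if overlaps(pk, ft):
                out.append(PeakAnnotation(i, j, feature_class(ft), "overlap"))
                hit = True
                continue
            win = _upstream_window(ft, upstream_max)
            if win is not None and overlaps(pk, win):
                out.append(PeakAnnotation(i, j, feature_class(ft), "upstream"))
                hit = True
        if not hit:
            out.append(PeakAnnotation(i, None, "unannotated", "unannotated"))
    return out


def feature_class_fractions(annotations: list) -> dict:
    """Fraction of peaks carrying at least one annotation of each class.
    Classes are not exclusive, so fractions need not sum to 1."""
    peak_ids = {a.peak_index for a in annotations}
    if not peak_ids:
        raise ValueError("empty peak set")
    n = len(peak_ids)
    out: dict = {}
    for cls in sorted({a.feature_class for a in annotations}):
        hit = {a.peak_index for a in annotations if a.feature_class == cls}
        out[cls] = len(hit) / n
    return out


def rpkm(count: float, feature_length_bp: float, library_size: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if feature_length_bp <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / (feature_length_bp / 1000.0 * library_size / 1e6)


@dataclass
class GenePropertyComparison:
    median_length_gain: float
    median_length_all: float
    p_length: float
    median_expr_gain: float
    median_expr_all: float
    p_expr: float

    @property
    def length_ratio(self) -> float:
        return self.median_length_gain / self.median_length_all

    @property
    def expr_ratio(self) -> float:
        return self.median_expr_gain / self.median_expr_all


def compare_gene_properties(gain_genes: list, all_genes: list,
                            expression: dict) -> GenePropertyComparison:
    """Median length and expression of gain genes vs the genome set, with
    two-sided Wilcoxon rank-sum p-values.  ``expression`` maps gene name
    to an expression value (e.g. RPKM) and must cover all genes."""
    if not gain_genes:
        raise ValueError("empty gain gene set")
    len_gain = np.array([float(len(g)) for g in gain_genes])
    len_all = np.array([float(len(g)) for g in all_genes])
    expr_gain = np.array([expression[g.name] for g in gain_genes])
    expr_all = np.array([expression[g.name] for g in all_genes])
    return GenePropertyComparison(
        median_length_gain=float(np.median(len_gain)),
        median_length_all=float(np.median(len_all)),
        p_length=float(ranksums(len_gain, len_all).pvalue),
        median_expr_gain=float(np.median(expr_gain)),
        median_expr_all=float(np.median(expr_all)),
        p_expr=float(ranksums(expr_gain, expr_all).pvalue),
    )
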