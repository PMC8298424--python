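"""Differential R-loop enrichment: TMM normalization, per-region NB
likelihood-ratio tests, threshold-based gain calls, mutant-specific /
common classification and G1-vs-S overlap categories.

Normalization follows the trimmed-mean-of-M-values recipe on genome-wide
200-bp count bins (trim 30% by M, 5% by A, inverse-variance weights,
factors rescaled to geometric mean 1).  Testing replaces a quasi-
likelihood F-test with an exact-null-free NB likelihood-ratio chi-square
(1 df) under a common dispersion, estimated by pooled method of moments
when both conditions are replicated and fixed (default 0.05) otherwise.
Enrichment thresholds are phase-specific: linear fold change > 1.2 and
-log10 p > 0.6 in S phase, > 2 and > 1 in G1 (strict inequalities); no
multiple-testing correction is applied, by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import BinnedCounts, Interval, merge_and_fuse, overlap_pairs
from .peaks import nb_logpmf

#: (linear fold change, -log10 p) thresholds per cell-cycle phase
THRESHOLDS = {"S": (1.2, 0.6), "G1": (2.0, 1.0)}


@dataclass
class NormalizationFactors:
    samples: list
    factors: np.ndarray
    reference: str
    trim_m: float = 0.30
    trim_a: float = 0.05

    def factor(self, sample: str) -> float:
        return float(self.factors[self.samples.index(sample)])


def tmm_factors(binned: BinnedCounts, trim_m: float = 0.30,
                trim_a: float = 0.05) -> NormalizationFactors:
    """TMM scale factors from a genome-wide bin count matrix.

    Bins with a zero count in any sample are excluded.  The reference is
    the sample whose upper-quartile count rate is closest to the mean of
    the upper quartiles.  Raises with fewer than 100 usable bins.
    """
    y = np.asarray(binned.counts, dtype=float)
    lib = np.asarray(binned.library_sizes, dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    usable = np.all(y > 0, axis=1)
    if usable.sum() < 100:
        raise ValueError(
            f"insufficient data for normalization: {int(usable.sum())} "
            "usable bins (< 100)"
        )
    y = y[usable]

    uq = np.array([np.quantile(y[:, s] / lib[s], 0.75)
                   for s in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for s in range(y.shape[1]):
        if s == ref:
            continue
        ys, ns = y[:, s], lib[s]
        m = np.log2((ys / ns) / (yr / nr))
        a = 0.5 * np.log2((ys / ns) * (yr / nr))
        if np.max(np.abs(m)) < 1e-6:  # identical profiles
            factors[s] = 1.0
            continue
        # asymptotic variance of M (delta method), used as weights 1/var
        var = (ns - ys) / (ns * ys) + (nr - yr) / (nr * yr)
        keep = (
            (m >= np.quantile(m, trim_m)) & (m <= np.quantile(m, 1 - trim_m))
            & (a >= np.quantile(a, trim_a)) & (a <= np.quantile(a, 1 - trim_a))
        )
        if keep.sum() == 0:
            keep = np.ones_like(keep)
        w = 1.0 / np.maximum(var[keep], 1e-12)
        factors[s] = 2.0 ** (np.sum(w * m[keep]) / np.sum(w))
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(list(binned.samples), factors,
                                binned.samples[ref], trim_m, trim_a)


@dataclass
class DifferentialResult:
    region: Interval
    mean_norm_1: float
    mean_norm_2: float
    log2fc: float  # condition2 over condition1
    p_value: float
    enriched: bool = False
    label: str = "none"

    @property
    def neg_log10_p(self) -> float:
        return -np.log10(self.p_value)

    @property
    def fold_change(self) -> float:
        return 2.0 ** self.log2fc


def results_to_frame(results: list) -> pd.DataFrame:
    rows = [
        dict(chrom=r.region.chrom, start=r.region.start, end=r.region.end,
             strand=r.region.strand, mean_norm_1=r.mean_norm_1,
             mean_norm_2=r.mean_norm_2, log2fc=r.log2fc, p_value=r.p_value,
             neg_log10_p=r.neg_log10_p, enriched=r.enriched, label=r.label)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "strand", "mean_norm_1", "mean_norm_2",
        "log2fc", "p_value", "neg_log10_p", "enriched", "label"])


def _nb_mle_mean(y, size, alpha, n_iter=60):
    """Per-row MLE of the common rate m in  y_ij ~ NB(size_ij * m, alpha).

    Damped fixed-point on the score equation; vectorized over rows.
    y, size: (R, S) arrays.  Returns (R,) rates.
    """
    tot_y = y.sum(axis=1)
    tot_s = size.sum(axis=1)
    m = np.maximum(tot_y / tot_s, 1e-12)
    for _ in range(n_iter):
        muh = size * m[:, None]
        w = 1.0 / (1.0 + alpha * muh)
        num = (w * y).sum(axis=1)
        den = (w * size).sum(axis=1)
        m_new = np.where(den > 0, num / np.maximum(den, 1e-300), m)
        m = np.maximum(m_new, 1e-12)
    return m


def estimate_dispersion(y_norm: np.ndarray, groups: list) -> float:
    """Pooled method-of-moments common dispersion from depth-normalized
    counts.  Each (region, condition) cell with >= 2 replicates provides
    a sample mean and variance; alpha solves sum(s2 - m) = alpha*sum(m^2)
    over all cells, floored at 1e-6."""
    num = 0.0
    den = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = y_norm[:, idx]
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum(s2[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if den <= 0:
        return 0.05
    return float(np.clip(num / den, 1e-6, 10.0))


def test_regions(region_counts: BinnedCounts, group1: list, group2: list,
                 factors: NormalizationFactors,
                 dispersion: float | str = "auto") -> list:
    """Per-region NB likelihood-ratio test of condition2 vs condition1.

    ``group1``/``group2`` name the samples of each condition.  Effective
    library size = library size x TMM factor; normalized counts are
    rescaled to the geometric mean of the effective sizes.  log2FC uses a
    0.5 pseudocount on each condition mean.  Regions with zero counts in
    all samples get log2FC = 0, p = 1.
    """
    samples = region_counts.samples
    i1 = [samples.index(s) for s in group1]
    i2 = [samples.index(s) for s in group2]
    y = np.asarray(region_counts.counts, dtype=float)
    lib = np.asarray(region_counts.library_sizes, dtype=float)
    fac = np.array([factors.factor(s) for s in samples])
    eff = lib * fac
    scale_to = np.exp(np.mean(np.log(eff[i1 + i2])))
    y_norm = y * (scale_to / eff)[None, :]

    if dispersion == "auto":
        alpha = (estimate_dispersion(y_norm, [i1, i2])
                 if min(len(i1), len(i2)) >= 2 else 0.05)
    else:
        alpha = float(dispersion)

    m1 = y_norm[:, i1].mean(axis=1)
    m2 = y_norm[:, i2].mean(axis=1)
    log2fc = np.log2((m2 + 0.5) / (m1 + 0.5))

    size = np.broadcast_to(eff / scale_to, y.shape)  # rate offsets
    r_null = _nb_mle_mean(y, size, alpha)
    r1 = _nb_mle_mean(y[:, i1], size[:, i1], alpha)
    r2 = _nb_mle_mean(y[:, i2], size[:, i2], alpha)

    def ll(yv, sv, rate):
        mu = sv * rate[:, None]
        return nb_logpmf(yv, mu, alpha).sum(axis=1)

    ll_null = ll(y[:, i1 + i2], size[:, i1 + i2], r_null)
    ll_alt = ll(y[:, i1], size[:, i1], r1) + ll(y[:, i2], size[:, i2], r2)
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = np.clip(chi2.sf(stat, df=1), 1e-300, 1.0)

    all_zero = y[:, i1 + i2].sum(axis=1) == 0
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.where(all_zero, 1.0, p)

    return [
        DifferentialResult(region=reg, mean_norm_1=float(m1[i]),
                           mean_norm_2=float(m2[i]), log2fc=float(log2fc[i]),
                           p_value=float(p[i]))
        for i, reg in enumerate(region_counts.regions)
    ]


def classify_enriched(results: list, phase: str) -> list:
    """Flag and return results passing the phase's gain thresholds
    (strict: FC > 1.2 and -log10 p > 0.6 in S; FC > 2, -log10 p > 1 in G1).
    Mutates the ``enriched`` field in place."""
    if phase not in THRESHOLDS:
        raise ValueError(f"unknown phase {phase!r}")
    fc_min, nlp_min = THRESHOLDS[phase]
    out = []
    for r in results:
        r.enriched = (r.fold_change > fc_min) and (r.neg_log10_p > nlp_min)
        if r.enriched:
            out.append(r)
    return out


def classify_specific_common(merged_results: list, phase: str = "S") -> list:
    """Label each merged-union region from a hpr1-vs-sen1 test
    (condition1 = sen1, condition2 = hpr1).

    hpr1-specific if enriched in hpr1 over sen1 by the phase thresholds,
    sen1-specific if enriched the other way, else common.  Mutates
    ``label`` in place and returns the results list.
    """
    if phase not in THRESHOLDS:
        raise ValueError(f"unknown phase {phase!r}")
    fc_min, nlp_min = THRESHOLDS[phase]
    for r in merged_results:
        fc = r.fold_change
        if fc > fc_min and r.neg_log10_p > nlp_min:
            r.label = "hpr1-specific"
        elif (1.0 / fc) > fc_min and r.neg_log10_p > nlp_min:
            r.label = "sen1-specific"
        else:
            r.label = "common"
    return merged_results


@dataclass(frozen=True)
class PhaseCategory:
    region: Interval
    category: str  # "G1" | "G1-S" | "S"


def phase_overlap_categories(g1_gain: list, s_gain: list) -> list:
    """Cross-phase overlap categories for one mutant's gain regions:
    G1 regions overlapping an S region are "G1-S", the rest "G1"; S
    regions untouched by any G1 region are "S"."""
    pairs = overlap_pairs(g1_gain, s_gain)
    g1_hit = {i for i, _ in pairs}
    s_hit = {j for _, j in pairs}
    out = [PhaseCategory(iv, "G1-S" if i in g1_hit else "G1")
           for i, iv in enumerate(g1_gain)]
    out += [PhaseCategory(iv, "S") for j, iv in enumerate(s_gain)
            if j not in s_hit]
    return out


def merged_test_regions(peaks_a: list, peaks_b: list,
                        fuse_dist: int = 200, stranded: bool = True) -> list:
    """Comparison regions: union of the two conditions' peak intervals,
    merged and fused when closer than ``fuse_dist``."""
    ivs = [p.interval if hasattr(p, "interval") else p
           for p in list(peaks_a) + list(peaks_b)]
    if not ivs:
        return []
    return merge_and_fuse(ivs, fuse_dist, stranded=stranded)
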