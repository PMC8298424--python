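"""Synthetic genomes, annotations, and signal tracks with planted truth.

The generator emulates a compact budding-yeast-like genome and the signal
structure of strand-specific DNA-RNA hybrid maps (DRIPc-seq) plus an
unstranded DNA-damage mark (gamma-H2A ChIP).  Conditions:

* ``WT`` — baseline: every gene carries sense-strand hybrid signal scaled
  by its expression, rising 5'->3' (linear ramp 0.5x to 1.5x of the gene
  mean), plus a weak flat antisense component and genome-wide background.
* ``hpr1`` — THO-depleted-like: planted gain regions (whole transcription
  units) multiply the local mean by ``f_gain`` in BOTH G1 and S phase,
  irrespective of orientation.
* ``sen1`` — helicase-depleted-like: gains appear in S phase ONLY, and a
  fraction ``pi_ho`` of them sit on head-on genes within 1 kb of an early
  replication origin (ARS) midpoint.
* ``+RNH`` — in-vitro RNase H treated control: all hybrid signal removed,
  background only.
* ``common`` gain regions gain in hpr1 (G1 and S) and in sen1 (S only).

Damage tracks put a Gaussian halo (sd ``sigma_dam``) around every gain
region active in the condition, splitting its mass ``a_dam`` downstream /
(1 - a_dam) upstream of the replication fork (fork direction = away from
the nearest ARS midpoint).  hpr1-like damage is symmetric (a = 0.5);
sen1-like uses the configured ``a_dam`` (default 0.8).

Counts are drawn at bin level from a negative binomial around the exact
expected-mean field, which is exposed as :func:`expected_mu` so tests can
assert on the noiseless construction directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import GenomeModel, Interval, ars_position

CONDITIONS = ("WT", "hpr1", "sen1", "+RNH")
PHASES = ("G1", "S")
GAIN_LABELS = ("hpr1-specific", "sen1-specific", "common")

_COND_CODE = {c: i for i, c in enumerate(CONDITIONS)}
_PHASE_CODE = {p: i for i, p in enumerate(PHASES)}


@dataclass
class TruthConfig:
    """Stated world for the generator.  Defaults are chosen once for a
    desk-scale genome on which every pipeline stage is exercisable; see
    docs/methods.md for the rationale of each value."""

    seed: int = 0
    n_chrom: int = 3
    chrom_length: int = 450_000
    n_genes: int = 450
    gene_length_meanlog: float = math.log(1400.0)
    gene_length_sdlog: float = 0.45
    gap_min: int = 400
    gap_mean: float = 600.0
    frac_trna: float = 0.05
    frac_snorna: float = 0.03
    telomere_length: int = 5000
    n_early_ars: int = 45
    min_ars_spacing: int = 20_000
    # signal model (per calling bin of `bin_width` bp)
    mu_bg: float = 5.0
    alpha_bg: float = 0.1
    gene_amp: float = 3.0
    expression_sdlog: float = 0.6
    antisense_fraction: float = 0.15
    f_gain: float = 3.0
    n_gain_hpr1: int = 40
    n_gain_sen1: int = 30
    n_gain_common: int = 25
    pi_ho: float = 0.8
    ars_max_dist: int = 1000
    # minimum midpoint spacing between gain genes active in the same
    # condition, so each damage halo (4 sigma_dam) is resolvable within
    # a +/- 5 kb metaplot window around its own anchor
    min_anchor_spacing: int = 9000
    # damage model (per h2ap_bin bp bin)
    sigma_dam: float = 1000.0
    a_dam: float = 0.8
    damage_mass: float = 3000.0
    h2ap_bg: float = 1.0
    h2ap_bin: int = 10
    # sequencing bookkeeping
    n_replicates: int = 2
    unique_fraction: float = 0.85

    def __post_init__(self):
        for name in ("pi_ho", "a_dam", "frac_trna", "frac_snorna",
                     "antisense_fraction", "unique_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.f_gain <= 1.0:
            raise ValueError("f_gain must exceed 1")
        for name in ("n_chrom", "chrom_length", "n_genes", "n_early_ars",
                     "n_gain_hpr1", "n_gain_sen1", "n_gain_common",
                     "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GainRegion:
    interval: Interval
    label: str  # one of GAIN_LABELS
    gene_index: int


@dataclass
class TruthTable:
    """Planted ground truth: annotation plus labeled gain regions."""

    config: TruthConfig
    genome: GenomeModel
    genes: list
    trnas: list
    snornas: list
    telomeres: list
    ars_midpoints: list  # 1-bp Intervals at origin midpoints
    gain_regions: list  # GainRegion
    expression: np.ndarray  # per-gene relative expression, mean ~1

    def features(self) -> list:
        return self.genes + self.trnas + self.snornas + self.telomeres

    def regions_with_label(self, label: str) -> list:
        return [g.interval for g in self.gain_regions if g.label == label]

    def damage_anchors(self, condition: str):
        """Gain regions whose hybrids (hence damage) are present in
        ``condition`` during S phase, and the asymmetry the condition
        imposes on the damage halo."""
        active = [g.interval for g in self.gain_regions
                  if gain_active(g.label, condition, "S")]
        a = 0.5 if condition == "hpr1" else self.config.a_dam
        return active, a


def gain_active(label: str, condition: str, phase: str) -> bool:
    """Does a planted region of class ``label`` gain hybrids in this
    (condition, phase)?  hpr1-class gains are cell-cycle blind; sen1-class
    gains require S phase; common regions follow both rules."""
    if condition in ("WT", "+RNH"):
        return False
    if label == "hpr1-specific":
        return condition == "hpr1"
    if label == "sen1-specific":
        return condition == "sen1" and phase == "S"
    if label == "common":
        return condition == "hpr1" or (condition == "sen1" and phase == "S")
    raise ValueError(f"unknown gain label {label!r}")


def _nearest_ars_direction(mid: float, chrom: str, ars_midpoints) -> str:
    """Fork direction at a locus: '+' right of the nearest origin
    midpoint (rightward-moving fork), '-' left of it."""
    best, fork = None, "+"
    for ars in ars_midpoints:
        if ars.chrom != chrom:
            continue
        pos = ars_position(ars)
        d = abs(mid - pos)
        if best is None or d < best:
            best = d
            fork = "+" if mid > pos else "-"
    if best is None:
        raise ValueError(f"no ARS on chromosome {chrom}")
    return fork


def _orientation(gene: Interval, ars_midpoints) -> str:
    """HO if transcription opposes the incoming fork, CD if it follows."""
    fork = _nearest_ars_direction(gene.midpoint, gene.chrom, ars_midpoints)
    return "CD" if gene.strand == fork else "HO"


def generate_annotation(config: TruthConfig) -> TruthTable:
    """Build the genome, features, origins, and planted gain regions.

    Deterministic given ``config.seed``.  Raises if the genome cannot host
    the requested feature counts (the failing constraint is named).
    """
    rng = np.random.default_rng([config.seed, 101])
    names = tuple(f"chr{'I' * (i + 1)}" for i in range(config.n_chrom))
    genome = GenomeModel(names, tuple([config.chrom_length] * config.n_chrom))

    telomeres = []
    for c in names:
        L = config.chrom_length
        t = config.telomere_length
        telomeres.append(Interval(c, 0, t, ".", f"{c}_telL", biotype="telomere"))
        telomeres.append(Interval(c, L - t, L, ".", f"{c}_telR", biotype="telomere"))

    # --- genes: sequential placement with exponential gaps -------------
    genes = []
    gaps = []  # intergenic gaps, for tRNA/snoRNA/ARS placement
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    for c, quota in zip(names, per_chrom):
        pos = config.telomere_length
        limit = config.chrom_length - config.telomere_length
        placed = 0
        while placed < quota:
            gap = config.gap_min + rng.exponential(config.gap_mean)
            glen = int(round(rng.lognormal(config.gene_length_meanlog,
                                           config.gene_length_sdlog)))
            glen = min(max(glen, 200), 20_000)
            start = int(round(pos + gap))
            if start + glen > limit:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{c}_g{placed}"
            genes.append(Interval(c, start, start + glen, strand, gid,
                                  biotype="gene"))
            gaps.append(Interval(c, int(pos), start, "."))
            pos = start + glen
            placed += 1
        if placed < quota:
            raise ValueError(
                f"genome too small: placed {placed}/{quota} genes on {c}; "
                "increase chrom_length or decrease n_genes"
            )
        gaps.append(Interval(c, int(pos), limit, "."))

    # --- small RNA genes in intergenic gaps ----------------------------
    def place_small(n, size, tag):
        wide = [g for g in gaps if len(g) >= size + 200]
        if len(wide) < n:
            raise ValueError(
                f"genome too small: only {len(wide)} gaps can host the "
                f"{n} requested {tag} features"
            )
        chosen = rng.choice(len(wide), size=n, replace=False)
        out = []
        for k, gi in enumerate(sorted(chosen)):
            g = wide[gi]
            mid = (g.start + g.end) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            out.append(Interval(g.chrom, mid - size // 2, mid + size - size // 2,
                                strand, f"{tag}{k}", biotype=f"{tag}_gene"))
        return out

    trnas = place_small(int(round(config.frac_trna * config.n_genes)), 80, "tRNA")
    snornas = place_small(int(round(config.frac_snorna * config.n_genes)), 150,
                          "snoRNA")

    # --- early origins: gap centres near evenly spaced targets ---------
    per_chrom_ars = [config.n_early_ars // config.n_chrom] * config.n_chrom
    for i in range(config.n_early_ars % config.n_chrom):
        per_chrom_ars[i] += 1
    ars = []
    for c, k in zip(names, per_chrom_ars):
        if k == 0:
            continue
        # prefer narrow gaps (origins are intergenic and usually sit
        # close to flanking promoters), so both neighbours fall inside
        # the ars_max_dist proximity rule; fall back to all gaps
        cgaps = sorted((g for g in gaps if g.chrom == c and len(g) >= 2),
                       key=lambda g: g.start)
        narrow = [g for g in cgaps
                  if len(g) <= 2 * max(config.ars_max_dist - 200, 1)]
        if len(narrow) >= 2 * k:
            cgaps = narrow
        centres = np.array([(g.start + g.end) // 2 for g in cgaps])
        # spread targets over the span genes actually occupy
        lo, hi = float(centres.min()), float(centres.max())
        targets = [lo + (hi - lo) * (j + 0.5) / k for j in range(k)]
        picked: list = []
        centres_sorted = np.sort(centres)
        for t in targets:  # targets increase left to right
            floor_pos = (picked[-1] + config.min_ars_spacing) if picked \
                else -np.inf
            cand = centres_sorted[centres_sorted >= floor_pos]
            if cand.size == 0:
                raise ValueError(
                    f"genome too small: cannot place {k} origins >= "
                    f"{config.min_ars_spacing} bp apart on {c}"
                )
            picked.append(int(cand[np.argmin(np.abs(cand - max(t, floor_pos)))]))
        for j, m in enumerate(sorted(picked)):
            ars.append(Interval(c, m, m + 1, ".", f"{c}_ARS{j}"))

    # --- expression, shared across conditions --------------------------
    expression = rng.lognormal(0.0, config.expression_sdlog, size=len(genes))

    # --- planted gain regions (whole gene bodies, disjoint genes) ------
    orient = [_orientation(g, ars) for g in genes]
    proximal = _ars_proximal_mask(genes, ars, config.ars_max_dist)
    ho_pool = [i for i in range(len(genes)) if proximal[i] and orient[i] == "HO"]

    n_ho = int(rng.binomial(config.n_gain_sen1, config.pi_ho))
    if n_ho > len(ho_pool):
        raise ValueError(
            f"genome too small: need {n_ho} head-on ARS-proximal genes for "
            f"sen1 gains but only {len(ho_pool)} exist"
        )

    # Gain genes active in the same condition keep their midpoints >=
    # min_anchor_spacing apart (hpr1 set = hpr1 + common, sen1 set =
    # sen1 + common) so each damage halo is attributable to its anchor.
    spacing = config.min_anchor_spacing

    def spaced(idx, mids):
        g = genes[idx]
        return all(g.chrom != c or abs(g.midpoint - m) >= spacing
                   for c, m in mids)

    def pick(pool, quota, *mid_sets, what=""):
        chosen = []
        for idx in rng.permutation(pool):
            idx = int(idx)
            if len(chosen) == quota:
                break
            if all(spaced(idx, ms) for ms in mid_sets):
                chosen.append(idx)
                for ms in mid_sets:
                    ms.append((genes[idx].chrom, genes[idx].midpoint))
        if len(chosen) < quota:
            raise ValueError(
                f"genome too small: placed {len(chosen)}/{quota} {what} "
                f"gain genes at >= {spacing} bp anchor spacing"
            )
        return chosen

    sen1_mids: list = []
    hpr1_mids: list = []
    sen1_ho = pick(ho_pool, n_ho, sen1_mids, what="sen1 head-on")
    taken = set(sen1_ho)
    rest_pool = [i for i in range(len(genes)) if i not in taken
                 and not (proximal[i] and orient[i] == "HO")]
    sen1_rest = pick(rest_pool, config.n_gain_sen1 - n_ho, sen1_mids,
                     what="sen1")
    sen1_idx = sorted(sen1_ho + sen1_rest)
    taken = set(sen1_idx)

    remaining = [i for i in range(len(genes)) if i not in taken]
    common_idx = sorted(pick(remaining, config.n_gain_common, sen1_mids,
                             hpr1_mids, what="common"))
    taken |= set(common_idx)
    remaining = [i for i in range(len(genes)) if i not in taken]
    hpr1_idx = sorted(pick(remaining, config.n_gain_hpr1, hpr1_mids,
                           what="hpr1"))

    gain_regions = (
        [GainRegion(genes[i], "hpr1-specific", i) for i in hpr1_idx]
        + [GainRegion(genes[i], "sen1-specific", int(i)) for i in sen1_idx]
        + [GainRegion(genes[i], "common", i) for i in common_idx]
    )
    gain_regions.sort(key=lambda g: g.interval.sort_key())

    return TruthTable(config, genome, genes, trnas, snornas, telomeres,
                      ars, gain_regions, expression)


def _ars_proximal_mask(genes, ars_midpoints, max_dist):
    mask = []
    for g in genes:
        d_best = None
        for a in ars_midpoints:
            if a.chrom != g.chrom:
                continue
            m = ars_position(a)
            if g.start <= m < g.end:
                d = 0.0
            elif m < g.start:
                d = g.start - m
            else:
                d = m - g.end
            d_best = d if d_best is None else min(d_best, d)
        mask.append(d_best is not None and d_best < max_dist)
    return mask


# ---------------------------------------------------------------------
# DRIPc-seq count simulation
# ---------------------------------------------------------------------

def expected_mu(truth: TruthTable, condition: str, phase: str,
                bin_width: int = 50) -> dict:
    """Noiseless per-bin expected counts, ``{strand: {chrom: array}}``.

    This is the exact mean field the sampler draws around, exposed so the
    construction itself is testable (e.g. sen1 gains never touch G1 means).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    cfg = truth.config
    genome = truth.genome
    mu = {s: {c: np.full(genome.n_bins(c, bin_width), cfg.mu_bg)
              for c in genome.chrom_names} for s in ("+", "-")}
    if condition == "+RNH":
        return mu  # hybrid signal removed in vitro: background only

    for gi, gene in enumerate(truth.genes):
        b0 = gene.start // bin_width
        b1 = -(-gene.end // bin_width)
        centres = (np.arange(b0, b1) + 0.5) * bin_width
        inside = (centres >= gene.start) & (centres < gene.end)
        if not inside.any():
            continue
        frac = (centres - gene.start) / len(gene)  # 0 at 5' for + genes
        if gene.strand == "-":
            frac = 1.0 - frac
        ramp = 0.5 + frac  # linear 0.5x -> 1.5x along 5'->3'
        level = cfg.mu_bg * cfg.gene_amp * truth.expression[gi]
        sense = mu[gene.strand][gene.chrom]
        anti = mu["-" if gene.strand == "+" else "+"][gene.chrom]
        idx = np.arange(b0, b1)[inside]
        sense[idx] += level * ramp[inside]
        anti[idx] += level * cfg.antisense_fraction

    for g in truth.gain_regions:
        if not gain_active(g.label, condition, phase):
            continue
        gene = truth.genes[g.gene_index]
        iv = g.interval
        b0 = iv.start // bin_width
        b1 = -(-iv.end // bin_width)
        centres = (np.arange(b0, b1) + 0.5) * bin_width
        inside = (centres >= iv.start) & (centres < iv.end)
        idx = np.arange(b0, b1)[inside]
        mu[gene.strand][iv.chrom][idx] *= cfg.f_gain
    return mu


@dataclass
class DripSample:
    """One simulated stranded DRIPc-seq library (raw binned counts)."""

    condition: str
    phase: str
    replicate: int
    plus: "object"  # CoverageTrack
    minus: "object"
    total_reads: float
    unique_reads: float

    def track(self, strand: str):
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"stranded sample has no {strand!r} track")

    @property
    def name(self) -> str:
        return f"{self.condition}_{self.phase}_rep{self.replicate}"


def _nb_draw(rng, mu, alpha):
    r = 1.0 / max(alpha, 1e-9)
    p = r / (r + np.asarray(mu, dtype=float))
    return rng.negative_binomial(r, p)


def simulate_drip_counts(truth: TruthTable, condition: str, phase: str,
                         replicate: int = 0, bin_width: int = 50,
                         seed: int | None = None) -> DripSample:
    """Draw one stranded binned-count library.

    Counts per bin are NB(mu, alpha_bg) around :func:`expected_mu`.
    Deterministic given (truth, condition, phase, replicate, seed); the
    planted truth never varies with the replicate index, only the noise.
    """
    from .core import CoverageTrack

    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    cfg = truth.config
    base = cfg.seed if seed is None else seed
    rng = np.random.default_rng(
        [base % (2**31), 7, _COND_CODE[condition], _PHASE_CODE[phase],
         int(replicate)]
    )
    mu = expected_mu(truth, condition, phase, bin_width)
    tracks = {}
    for strand in ("+", "-"):
        data = {c: _nb_draw(rng, mu[strand][c], cfg.alpha_bg).astype(float)
                for c in truth.genome.chrom_names}
        tracks[strand] = CoverageTrack(truth.genome, bin_width, data,
                                       strand=strand, normalization="raw")
    total = tracks["+"].total() + tracks["-"].total()
    unique = round(cfg.unique_fraction * total)
    for t in tracks.values():
        t.total_reads = total
        t.unique_reads = unique
    return DripSample(condition, phase, replicate, tracks["+"], tracks["-"],
                      total, unique)


# ---------------------------------------------------------------------
# gamma-H2A damage track simulation
# ---------------------------------------------------------------------

def expected_h2ap_mu(truth: TruthTable, condition: str) -> dict:
    """Noiseless expected damage coverage per h2ap bin, per chromosome."""
    cfg = truth.config
    bw = cfg.h2ap_bin
    genome = truth.genome
    mu = {c: np.full(genome.n_bins(c, bw), cfg.h2ap_bg)
          for c in genome.chrom_names}
    if condition in ("WT", "+RNH"):
        return mu
    anchors, a = truth.damage_anchors(condition)
    sig = cfg.sigma_dam
    for iv in anchors:
        fork = _nearest_ars_direction(iv.midpoint, iv.chrom, truth.ars_midpoints)
        n = len(mu[iv.chrom])
        span = int(4 * sig // bw) + 1
        mid_bin = int(iv.midpoint // bw)
        b0, b1 = max(0, mid_bin - span), min(n, mid_bin + span + 1)
        x = (np.arange(b0, b1) + 0.5) * bw - iv.midpoint
        downstream = x > 0 if fork == "+" else x < 0
        w = np.where(downstream, a, 1.0 - a)
        kernel = (2.0 * cfg.damage_mass * w * bw
                  * np.exp(-0.5 * (x / sig) ** 2) / (sig * math.sqrt(2 * math.pi)))
        mu[iv.chrom][b0:b1] += kernel
    return mu


def simulate_h2ap_track(truth: TruthTable, condition: str,
                        seed: int | None = None):
    """One unstranded damage (gamma-H2A ChIP) coverage track, plus the
    matched WT track drawn from an independent substream."""
    from .core import CoverageTrack

    cfg = truth.config
    base = cfg.seed if seed is None else seed

    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")

    def draw(cond, stream):
        rng = np.random.default_rng([base % (2**31), 11, _COND_CODE[cond], stream])
        mu = expected_h2ap_mu(truth, cond)
        data = {c: _nb_draw(rng, mu[c], cfg.alpha_bg).astype(float)
                for c in truth.genome.chrom_names}
        t = CoverageTrack(truth.genome, cfg.h2ap_bin, data, strand=".",
                          normalization="raw")
        t.total_reads = t.total()
        t.unique_reads = round(cfg.unique_fraction * t.total_reads)
        return t

    return draw(condition, 0), draw("WT", 1)
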