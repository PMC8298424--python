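# Methods

## Coordinate model

All coordinates are 0-based half-open; GFF3 input (1-based inclusive) is
converted on read. Coverage lives on fixed bin grids stored dense per
chromosome — cheap at yeast scale and unambiguous: bedGraph input that does
not align to the grid is rejected, never resampled. Stranded assays (hybrid
maps) are processed per strand throughout; the damage mark is unstranded.
"Closer than" thresholds (200 bp fuse distance, 200 bp upstream annotation
window, 1 kb origin proximity) are strict inequalities.

## Peak calling

A two-state hidden Markov model with negative-binomial emissions
(mean/dispersion form, Var = μ + αμ²) is fitted per strand and replicate by
EM. The E-step is exact scaled forward–backward (chromosomes are independent
chains sharing parameters; numba-accelerated when available). The M-step
updates transitions and initial probabilities in closed form; for each
state, the mean update is the posterior-weighted mean (the conditional MLE)
and the dispersion starts from the posterior-weighted method-of-moments
value and is polished by a bounded 1-D conditional maximization of the
weighted NB likelihood. Every step is therefore a true (E)CM step and the
log-likelihood is non-decreasing — an invariant the tests assert. EM stops
when the relative log-likelihood change falls below 1e−4 (default) or at
200 iterations (non-convergence is logged, best parameters returned).

Candidate peaks are maximal runs of bins with enriched-state posterior
> 0.5. A run is kept only if its **maximum** posterior reaches 0.99999 and
its length reaches 100 bp; coordinates snap to bin boundaries. The calling
bin width defaults to 50 bp: the 100 bp minimum-length filter needs
sub-100 bp resolution, and hybrids at this depth are well sampled at 50 bp.
A fit whose two state means collapse within 5% is flagged degenerate and
yields no peaks (a constant track carries no separable enrichment).
Replicate consensus is the pairwise intersection of overlapping peaks,
scored with the weaker replicate's posterior; a multivariate joint HMM
across replicates would share information earlier but has the same output
contract, and the consensus filter is what downstream stages consume.

Zero inflation is not modelled; at these depths the NB dispersion absorbs
the extra zeros. This is a deliberate simplification.

## Normalization and differential testing

Composition-robust scale factors are computed by trimmed mean of M-values
on genome-wide 200-bp bins (strands pooled): bins with a zero in any sample
are dropped; the reference is the sample whose upper-quartile rate is
closest to the panel mean; per-bin log-ratios are trimmed 30% by M and 5%
by A and averaged with inverse-variance weights; factors are rescaled to
geometric mean 1. The implementation agrees with edgeR's `calcNormFactors`
within 1% on shared inputs (cross-checked in the tests via Rscript).

Comparison regions are the merged (< 200 bp fused) peak unions of the two
conditions. Region counts are tested with an NB likelihood-ratio test:
rates fitted by damped Fisher scoring with effective-library offsets
(library size × TMM factor), statistic referred to χ²(1). The common
dispersion is pooled method-of-moments across all regions when both
conditions have ≥ 2 replicates (each region×condition cell contributes its
sample mean and variance), otherwise a fixed 0.05. A quasi-likelihood
F-test would be slightly more conservative at n = 2; the LRT's type-I error
is calibrated in the tests (4.9% at nominal 5% over 2000 null regions).
log2FC uses a 0.5 pseudocount per condition mean so zero-count regions stay
finite. No multiple-testing correction is applied: enrichment is defined on
raw thresholds (FC > 1.2 and −log₁₀ p > 0.6 in S phase; FC > 2 and
−log₁₀ p > 1 in G1, both strict), matching the analysis this package
reimplements; FDR control is intentionally out of scope.

Mutant-specific vs common classification re-tests the merged union of both
mutants' gain regions directly mutant-vs-mutant with the same thresholds
(hpr1-specific if enriched in hpr1 over sen1, sen1-specific if the
reverse, else common). G1/S categories are pure interval overlap: a G1
gain overlapping any S gain is "G1-S", else "G1"; S gains untouched by G1
are "S".

## Metaprofiles and the asymmetry index

Coverage for profiling is RPKM at 10-bp bins. RNase-H-treated samples are
rescaled by unique/total mapped reads before comparison. WT subtraction is
elementwise and **not clamped** — regions where WT exceeds the mutant stay
negative, which matters for honest averaging.

Reference-point profiles sample a fixed window around each anchor midpoint
(midpoint rather than scaled body: symmetric, robust to peak length);
scaled-region profiles rescale the body to a fixed bin count with
fixed-resolution flanks. Rows are flipped so the axis runs 5′→3′ of the
anchor, or fork-upstream→fork-downstream when oriented by fork direction
(fork = away from the nearest early-origin midpoint, strictly bidirectional,
no termination model). Windows that leave the chromosome are NaN-padded;
fully off-chromosome anchors are dropped and logged.

The asymmetry index per anchor is AI = (D − U)/(D + U), where U and D are
the mean flank signals up/downstream excluding the anchor's own body (so AI
measures spreading, not the peak). Negative flank means (possible after WT
subtraction) are floored at zero; anchors with no flank signal are excluded
and counted. The summary is the mean AI with a 1000-resample bootstrap 95%
CI. For a half-Gaussian damage halo splitting mass a downstream/(1 − a)
upstream, the plug-in expectation is AI = 2a − 1, which the generator
recovery tests confirm (a = 0.8 → 0.6 ± 0.02 at default sizes).

## Orientation analysis

Genes whose nearest edge lies strictly within 1 kb of an early-origin
midpoint are assigned to that origin (ties to the lower coordinate). The
gene's side is the sign of (gene midpoint − origin midpoint); a gene
midpoint exactly on the origin midpoint is ambiguous and excluded
explicitly. Codirectional means gene strand equals fork direction. Gain ×
orientation 2×2 tables use ≥ 1 bp overlap with a gain region. The χ²
statistic is the closed-form 2×2 formula without continuity correction; the
one-sided p halves the two-sided tail when the observed direction matches
the alternative (1 − half otherwise) — a 1-df χ² has no native sidedness,
so this is the standard directional interpretation.

## The synthetic world

The generator emulates the features of real stranded hybrid and damage data
that the pipeline's contracts depend on, with these defaults:

| parameter | default | why |
|---|---|---|
| genome | 3 × 450 kb | desk-scale but multi-chromosome |
| genes | 450, log-normal length (median 1.4 kb, σ_log 0.45) | yeast-like gene size/density |
| intergenic gaps | 400 + Exp(600) bp | yeast-like spacing; ≥ 400 bp keeps distinct units from fusing under the 200 bp rule, so planted labels stay attributable |
| early origins | 45, ≥ 20 kb apart, centred in narrow gaps | origins are intergenic and promoter-proximal; guarantees a head-on proximal gene pool |
| background | NB(μ = 5, α = 0.1) per 50 bp bin | low-coverage noise floor |
| gene signal | 3 × background × LogNormal(0, 0.6) expression, linear 0.5×→1.5× 5′→3′ ramp on the sense strand; 0.15 flat antisense | hybrids rise toward the 3′ end; expression is shared across conditions so it never confounds differential calls |
| gains | ×3 multiplier over whole transcription units; 40 hpr1-class (G1+S), 30 sen1-class (S-only, 80% on head-on origin-proximal genes), 25 common | comfortable detectability; effect sizes are a modelling choice, not data-derived |
| anchor spacing | gain genes of one condition ≥ 9 kb apart | each damage halo (σ 1 kb) resolvable within its own ±5 kb window |
| damage | Gaussian halo σ = 1 kb, 3000 expected reads/anchor over NB(1, 0.1) per 10 bp bin; mass split a/(1 − a) by fork side, a = 0.5 (hpr1-like) / 0.8 (sen1-like) | damage spreads kilobases from hybrid sites; symmetric vs fork-downstream spreading is the discriminating signature |
| RNase-H sample | background only; unique/total = 0.85 | hybrid-specificity control |
| replicates | 2 per condition | the consensus contract |

Counts are drawn directly at bin level (no read placement): the pipeline
consumes binned counts, so read-level simulation would add nothing
testable. Everything is deterministic given (config, seed); replicate
indices change only the noise stream, never the planted truth. The exact
expected-mean fields (`expected_mu`, `expected_h2ap_mu`) are public so
tests can assert on the noiseless construction.

**What a green test does not establish.** The generator has no GC or
mappability bias, no fragment-length model, no replication-timing gradient,
no termination zones, and plants gains as whole transcription units with a
single global fold change. Recovery rates near 100% here say the
implementation is correct on its stated world, not that real libraries
would be called with that sensitivity.

## Numerical choices and degenerate inputs

- NB log-pmf via gammaln (continuous in the count argument); dispersions
  clipped to [1e−8, 50].
- Rate MLEs by 60 damped fixed-point iterations, vectorized over regions;
  LRT statistics floored at 0; p-values floored at 1e−300.
- All-zero regions: log2FC = 0, p = 1 (not an error). All-zero HMM tracks:
  error. Fewer than 100 usable TMM bins: error. Empty origin set: error.
- Bootstrap and simulation seeds always flow from the caller's seed.

## Known limitations

- Single-replicate designs skip consensus and use the fixed dispersion;
  inference there is honest but weak.
- The HO/CD model ignores fork termination and replication timing; every
  locus is assigned to its nearest early origin.
- Metaplot sampling is piecewise-constant (bin lookup), so profiles carry
  bin-resolution jitter; mirror symmetry is exact only for windows sampled
  at bin centres.
- The asymmetry index attenuates when anchors are detected regions whose
  midpoints are offset from the true hybrid site (observed ≈ 0.5 vs 0.6
  planted at default sizes); anchoring on planted truth recovers the
  plug-in value.
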