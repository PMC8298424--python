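"""Two-state negative-binomial HMM peak calling on stranded binned counts.

A background and an enriched state with NB emissions (mean/dispersion
parameterization, var = mu + alpha*mu^2) are fitted by EM: exact
forward-backward with per-position scaling for the E-step, posterior-
weighted method-of-moments updates for the NB parameters.  Chromosomes
are independent chains sharing parameters.  Candidate peaks are maximal
runs of bins whose enriched-state posterior exceeds 0.5; a run becomes a
peak only if its maximum posterior reaches the cutoff (default 0.99999)
and its length reaches the minimum (default 100 bp) — short or weakly
supported runs are discarded.  Replicate consensus keeps only intervals
supported by both replicates (pairwise intersections).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import CoverageTrack, Interval

log = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def nb_logpmf(k, mu, alpha):
    """NB log-pmf in (mean, dispersion) form, continuous in k via gammaln."""
    k = np.asarray(k, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    r = 1.0 / max(float(alpha), 1e-9)
    logp = np.log(r) - np.log(r + mu)
    log1mp = np.log(mu) - np.log(r + mu)
    return (gammaln(k + r) - gammaln(r) - gammaln(k + 1.0)
            + r * logp + k * log1mp)


def _optimize_alpha(x, w, mu, alpha0):
    """Posterior-weighted conditional MLE of the NB dispersion for a
    fixed mean: 1-D bounded maximization over log(alpha), warm-started
    at the method-of-moments value."""
    from scipy.optimize import minimize_scalar

    def neg_q(log_a):
        return -float((w * nb_logpmf(x, mu, np.exp(log_a))).sum())

    lo, hi = np.log(1e-8), np.log(50.0)
    res = minimize_scalar(neg_q, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    best = float(np.exp(res.x))
    # never accept a worse value than the warm start
    if neg_q(np.log(max(alpha0, 1e-8))) < res.fun:
        return alpha0
    return best


def _fb_python(logb, log_t, log_pi):
    """Scaled forward-backward; reference implementation."""
    n, S = logb.shape
    shift = logb.max(axis=1)
    b = np.exp(logb - shift[:, None])
    T = np.exp(log_t)
    pi = np.exp(log_pi)
    alpha = np.empty((n, S))
    c = np.empty(n)
    alpha[0] = pi * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ T) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((n, S))
    beta[-1] = 1.0
    xi = np.zeros((S, S))
    for t in range(n - 2, -1, -1):
        beta[t] = (T @ (b[t + 1] * beta[t + 1])) / c[t + 1]
        xi += (alpha[t][:, None] * T * (b[t + 1] * beta[t + 1])[None, :]
               / c[t + 1])
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    ll = float(np.log(c).sum() + shift.sum())
    return gamma, xi, ll


if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _fb_numba(logb, T, pi):  # pragma: no cover - numba-compiled
        n, S = logb.shape
        alpha = np.empty((n, S))
        c = np.empty(n)
        b = np.empty((n, S))
        shift_sum = 0.0
        for t in range(n):
            m = logb[t, 0]
            for s in range(1, S):
                if logb[t, s] > m:
                    m = logb[t, s]
            shift_sum += m
            for s in range(S):
                b[t, s] = np.exp(logb[t, s] - m)
        tot = 0.0
        for s in range(S):
            alpha[0, s] = pi[s] * b[0, s]
            tot += alpha[0, s]
        c[0] = tot
        for s in range(S):
            alpha[0, s] /= tot
        for t in range(1, n):
            tot = 0.0
            for s in range(S):
                acc = 0.0
                for r in range(S):
                    acc += alpha[t - 1, r] * T[r, s]
                alpha[t, s] = acc * b[t, s]
                tot += alpha[t, s]
            c[t] = tot
            for s in range(S):
                alpha[t, s] /= tot
        beta = np.empty((n, S))
        for s in range(S):
            beta[n - 1, s] = 1.0
        xi = np.zeros((S, S))
        for t in range(n - 2, -1, -1):
            for s in range(S):
                acc = 0.0
                for u in range(S):
                    acc += T[s, u] * b[t + 1, u] * beta[t + 1, u]
                beta[t, s] = acc / c[t + 1]
            for s in range(S):
                for u in range(S):
                    xi[s, u] += (alpha[t, s] * T[s, u] * b[t + 1, u]
                                 * beta[t + 1, u] / c[t + 1])
        gamma = alpha * beta
        for t in range(n):
            tot = 0.0
            for s in range(S):
                tot += gamma[t, s]
            for s in range(S):
                gamma[t, s] /= tot
        ll = shift_sum
        for t in range(n):
            ll += np.log(c[t])
        return gamma, xi, ll


def _forward_backward(logb, T, pi):
    if _HAVE_NUMBA:
        return _fb_numba(logb, T, pi)
    return _fb_python(logb, np.log(T), np.log(pi))


@dataclass
class HMMParams:
    """Fitted emission/transition parameters of the two-state model.
    State 0 is background, state 1 enriched (mu[1] > mu[0] enforced)."""

    mu: np.ndarray
    alpha: np.ndarray
    transition: np.ndarray
    startprob: np.ndarray
    loglik: float
    loglik_trace: list
    n_iter: int
    converged: bool

    @property
    def degenerate(self) -> bool:
        """True when the two states collapsed (means within 5%): the
        track carries no separable enrichment and no peaks should be
        called from it."""
        lo, hi = float(self.mu[0]), float(self.mu[1])
        return hi <= 1.05 * lo


@dataclass(frozen=True)
class Peak:
    interval: Interval
    max_posterior: float
    mean_signal: float


def fit_nb_hmm(track: CoverageTrack, max_iter: int = 200, tol: float = 1e-4):
    """EM fit of the two-state NB HMM to one strand's binned counts.

    Returns (HMMParams, posteriors) where ``posteriors[chrom]`` is the
    per-bin posterior probability of the enriched state.  Raises on an
    all-zero track; warns (and returns the best parameters) when EM does
    not converge within ``max_iter``.
    """
    chroms = list(track.genome.chrom_names)
    xs = [np.asarray(track.data[c], dtype=float) for c in chroms]
    allx = np.concatenate(xs)
    if allx.sum() == 0:
        raise ValueError("degenerate input: all-zero track")
    n_total = allx.size
    if n_total < 1000:
        warnings.warn(f"only {n_total} bins; HMM fit may be unstable")

    # moment-based init: low/high quantiles, mildly sticky transitions
    mu = np.array([
        max(np.quantile(allx, 0.40), 0.1),
        max(np.quantile(allx, 0.99), np.quantile(allx, 0.40) * 2 + 1.0),
    ])
    alpha = np.array([0.1, 0.1])
    T = np.array([[0.99, 0.01], [0.10, 0.90]])
    pi = np.array([0.9, 0.1])

    trace = []
    converged = False
    gammas = None
    for it in range(max_iter):
        ll = 0.0
        xi_acc = np.zeros((2, 2))
        gammas = []
        pi_acc = np.zeros(2)
        for x in xs:
            logb = np.stack([nb_logpmf(x, mu[s], alpha[s]) for s in (0, 1)],
                            axis=1)
            g, xi, l = _forward_backward(logb, T, pi)
            gammas.append(g)
            xi_acc += xi
            pi_acc += g[0]
            ll += l
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
        # M-step: transition rows, initial distribution, NB emissions.
        # The mean update (posterior-weighted mean) is the exact MLE for
        # fixed dispersion; the dispersion starts from the posterior-
        # weighted method-of-moments value and is then polished by a 1-D
        # conditional maximization, so every EM step is a true (E)CM step
        # and the log-likelihood is non-decreasing.
        T = xi_acc / xi_acc.sum(axis=1, keepdims=True)
        T = np.clip(T, 1e-8, 1 - 1e-8)
        T /= T.sum(axis=1, keepdims=True)
        pi = pi_acc / pi_acc.sum()
        pi = np.clip(pi, 1e-8, 1.0)
        pi /= pi.sum()
        g_all = np.concatenate(gammas, axis=0)
        for s in (0, 1):
            w = g_all[:, s]
            wsum = w.sum()
            if wsum < 1e-8:
                continue
            m = float((w * allx).sum() / wsum)
            v = float((w * (allx - m) ** 2).sum() / wsum)
            mu[s] = max(m, 1e-3)
            a_mom = min(max((v - m) / (m * m), 1e-8), 50.0)
            alpha[s] = _optimize_alpha(allx, w, mu[s], a_mom)
        if mu[1] < mu[0]:  # keep enriched = state 1
            mu, alpha = mu[::-1].copy(), alpha[::-1].copy()
            T = T[::-1, ::-1].copy()
            pi = pi[::-1].copy()
            gammas = [g[:, ::-1].copy() for g in gammas]

    if not converged:
        log.warning("NB-HMM EM did not converge in %d iterations "
                    "(|dll| = %.3g)", max_iter,
                    abs(trace[-1] - trace[-2]) if len(trace) > 1 else np.nan)

    params = HMMParams(mu=mu.copy(), alpha=alpha.copy(), transition=T.copy(),
                       startprob=pi.copy(), loglik=trace[-1],
                       loglik_trace=trace, n_iter=len(trace),
                       converged=converged)
    posteriors = {c: gammas[i][:, 1].copy() for i, c in enumerate(chroms)}
    return params, posteriors


def call_peaks(posteriors: dict, genome, bin_width: int,
               cutoff: float = 0.99999, min_length: int = 100,
               strand: str = ".", signal: CoverageTrack | None = None) -> list:
    """Turn enriched-state posteriors into peaks.

    Candidate runs are maximal stretches with posterior > 0.5; a run is
    kept iff its maximum posterior >= ``cutoff`` and its bp length >=
    ``min_length``.  Coordinates snap to bin boundaries.
    """
    peaks = []
    for chrom, p in posteriors.items():
        p = np.asarray(p)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("posteriors must lie in [0, 1]")
        above = p > 0.5
        if not above.any():
            continue
        d = np.diff(above.astype(int))
        starts = list(np.where(d == 1)[0] + 1)
        ends = list(np.where(d == -1)[0] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(p))
        clen = genome.length(chrom)
        for b0, b1 in zip(starts, ends):
            start, end = b0 * bin_width, min(b1 * bin_width, clen)
            if end - start < min_length:
                continue
            mp = float(p[b0:b1].max())
            if mp < cutoff:
                continue
            iv = Interval(chrom, start, end, strand)
            ms = (signal.region_sum(iv) / (b1 - b0)) if signal is not None \
                else float("nan")
            peaks.append(Peak(iv, mp, ms))
    peaks.sort(key=lambda pk: pk.interval.sort_key())
    return peaks


def call_peaks_on_track(track: CoverageTrack, cutoff: float = 0.99999,
                        min_length: int = 100, max_iter: int = 200,
                        tol: float = 1e-4) -> list:
    """Fit + call on one strand's counts; returns [] on a degenerate fit
    (collapsed states mean there is no enrichment to call)."""
    params, post = fit_nb_hmm(track, max_iter=max_iter, tol=tol)
    if params.degenerate:
        log.info("degenerate HMM fit (mu_B=%.3g, mu_E=%.3g): no peaks",
                 params.mu[0], params.mu[1])
        return []
    return call_peaks(post, track.genome, track.bin_width, cutoff,
                      min_length, strand=track.strand, signal=track)


def consensus_peaks(peaks_rep1: list, peaks_rep2: list) -> list:
    """Peaks supported by both replicates: pairwise intersections of
    overlapping peaks, scored by the weaker replicate's posterior."""
    out = []
    by_chrom: dict = {}
    for pk in peaks_rep2:
        by_chrom.setdefault(pk.interval.chrom, []).append(pk)
    for lst in by_chrom.values():
        lst.sort(key=lambda pk: pk.interval.start)
    for p1 in peaks_rep1:
        for p2 in by_chrom.get(p1.interval.chrom, []):
            a, b = p1.interval, p2.interval
            if b.start >= a.end:
                break
            if a.start < b.end and b.start < a.end:
                iv = Interval(a.chrom, max(a.start, b.start),
                              min(a.end, b.end), a.strand)
                ms = np.nanmean([p1.mean_signal, p2.mean_signal])
                out.append(Peak(iv, min(p1.max_posterior, p2.max_posterior),
                                float(ms)))
    out.sort(key=lambda pk: pk.interval.sort_key())
    return out
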