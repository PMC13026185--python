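"""Census size from capture-with-replacement likelihoods (equal-rate and
two-innate-rate models), parametric-bootstrap model selection and CIs, and
effective size from linkage disequilibrium.

The two-rate likelihood sums over assignments of the observed individuals
to the fast/slow classes via elementary symmetric polynomials, so it
reduces exactly to the equal-rate likelihood at rate ratio alpha = 1 for
every (N, a).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as chi2_dist

from .identity import MultilocusGenotype


@dataclass
class CaptureCounts:
    counts: List[int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty capture-count vector")
        if any(c < 1 for c in self.counts):
            raise ValueError("all capture counts must be >= 1")

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def t(self) -> int:
        return sum(self.counts)


@dataclass
class EcmFit:
    n_hat: int
    loglik: float
    boundary: bool
    profile: Dict[int, float]


@dataclass
class TirmFit:
    n_hat: int
    n_easy: int
    alpha: float
    loglik: float
    boundary: bool


def _lff(x: float, m: int) -> float:
    """log falling factorial x!/(x-m)!"""
    return gammaln(x + 1) - gammaln(x - m + 1)


def ecm_loglik(counts: CaptureCounts, n: int) -> float:
    """log L(N) = log[N!/(N-k)!] - t log N (multinomial coefficient dropped)."""
    if n < counts.k:
        return -math.inf
    return _lff(n, counts.k) - counts.t * math.log(n)


def ecm_mle(counts: CaptureCounts, max_n: int = 25) -> EcmFit:
    """Exhaustive integer scan of the equal-capture likelihood on [k, max_n]."""
    if max_n < counts.k:
        raise ValueError(f"max_n={max_n} below number of observed individuals {counts.k}")
    profile = {n: ecm_loglik(counts, n) for n in range(counts.k, max_n + 1)}
    n_hat = max(profile, key=lambda n: (profile[n], -n))
    return EcmFit(n_hat=n_hat, loglik=profile[n_hat],
                  boundary=(n_hat == max_n), profile=profile)


def _log_esp(log_x: np.ndarray) -> np.ndarray:
    """log elementary symmetric polynomials e_0..e_k of exp(log_x)."""
    k = log_x.size
    e = np.full(k + 1, -np.inf)
    e[0] = 0.0
    for i in range(k):
        e[1:i + 2] = np.logaddexp(e[1:i + 2], e[0:i + 1] + log_x[i])
    return e


def tirm_loglik(counts: CaptureCounts, n: int, a: int, alpha: float) -> float:
    """Two-class likelihood marginalized over class assignments.

    Class A has a members with capture weight alpha >= 1; class B has n - a
    members with weight 1.  Sums over which observed individuals belong to
    class A using elementary symmetric polynomials of alpha^{c_i}.
    """
    if n < counts.k or not 0 <= a <= n or alpha < 1.0 - 1e-12:
        return -math.inf
    c = np.asarray(counts.counts, dtype=float)
    k, t = counts.k, counts.t
    log_e = _log_esp(c * math.log(alpha))
    lo = max(0, k - (n - a))
    hi = min(a, k)
    if lo > hi:
        return -math.inf
    ka = np.arange(lo, hi + 1)
    terms = (_lff(a, ka) + _lff(n - a, k - ka) + log_e[ka])
    denom = a * alpha + (n - a)
    return float(logsumexp(terms) - t * math.log(denom))


def _tirm_scan(counts: CaptureCounts, max_n: int, alphas: np.ndarray
               ) -> Tuple[int, int, float, float]:
    c = np.asarray(counts.counts, dtype=float)
    k, t = counts.k, counts.t
    cells = np.array([(n, a) for n in range(k, max_n + 1) for a in range(0, n + 1)])
    n_arr, a_arr = cells[:, 0], cells[:, 1]
    ka = np.arange(k + 1)

    # log falling factorials [x]_m for x in 0..max_n, m in 0..k (-inf when m > x)
    xs = np.arange(max_n + 1)
    with np.errstate(invalid="ignore"):
        lff_tab = gammaln(xs[:, None] + 1) - gammaln(xs[:, None] - ka[None, :] + 1)
    lff_tab[ka[None, :] > xs[:, None]] = -np.inf

    # assignment-independent part: [a]_ka + [n-a]_{k-ka}, (cells x ka)
    fixed = lff_tab[a_arr][:, ka] + lff_tab[n_arr - a_arr][:, k - ka]

    best = (-math.inf, counts.k, 0, 1.0)
    log_na = np.log(np.outer(a_arr, alphas - 1.0) + n_arr[:, None])
    for ai, alpha in enumerate(alphas):
        log_e = _log_esp(c * math.log(alpha))
        terms = fixed + log_e[None, :]
        m = terms.max(axis=1)
        ll = m + np.log(np.exp(terms - m[:, None]).sum(axis=1)) - t * log_na[:, ai]
        i = int(np.argmax(ll))
        if ll[i] > best[0] + 1e-12:
            best = (float(ll[i]), int(n_arr[i]), int(a_arr[i]), float(alpha))
    return best[1], best[2], best[3], best[0]


def tirm_mle(counts: CaptureCounts, max_n: int = 25,
             alpha_max: float = 40.0, refine: bool = True) -> TirmFit:
    """Exhaustive (N, a) grid with a geometric alpha scan plus continuous
    refinement of alpha at the best cell (``refine=False`` for bootstrap
    loops, where the grid optimum is sufficient and consistent)."""
    if max_n < counts.k:
        raise ValueError(f"max_n={max_n} below number of observed individuals {counts.k}")
    alphas = np.concatenate([[1.0], np.geomspace(1.02, alpha_max, 40)])
    n_hat, a_hat, alpha0, ll0 = _tirm_scan(counts, max_n, alphas)

    best = (ll0, n_hat, a_hat, alpha0)
    if refine:
        for n, a in {(n_hat, a_hat), (n_hat, max(0, a_hat - 1)),
                     (n_hat, min(n_hat, a_hat + 1))}:
            res = minimize_scalar(
                lambda x: -tirm_loglik(counts, n, a, x),
                bounds=(1.0, alpha_max), method="bounded",
                options={"xatol": 1e-6})
            if -res.fun > best[0]:
                best = (-res.fun, n, a, float(res.x))
    ll, n_hat, a_hat, alpha = best
    return TirmFit(n_hat=n_hat, n_easy=a_hat, alpha=alpha, loglik=ll,
                   boundary=(n_hat == max_n))


def _simulate_counts_ecm(rng: np.random.Generator, n: int, t: int) -> CaptureCounts:
    draws = rng.integers(0, n, size=t)
    counts = np.bincount(draws, minlength=n)
    return CaptureCounts([int(c) for c in counts if c > 0])


def _simulate_counts_tirm(rng: np.random.Generator, n: int, a: int,
                          alpha: float, t: int) -> CaptureCounts:
    w = np.concatenate([np.full(a, alpha), np.ones(n - a)])
    draws = rng.choice(n, size=t, p=w / w.sum())
    counts = np.bincount(draws, minlength=n)
    return CaptureCounts([int(c) for c in counts if c > 0])


def model_select_lrt(
    counts: CaptureCounts,
    max_n: int = 25,
    n_boot: int = 100,
    seed: int = 0,
) -> Tuple[str, float, float]:
    """Parametric bootstrap LRT of the two-rate model against equal rates.

    Lambda = 2(lnL_TIRM - lnL_ECM) >= 0 by nesting; the null distribution
    comes from datasets simulated under the fitted equal-rate model.
    Returns (chosen model, p, observed Lambda); TIRM is chosen iff p < 0.05.
    """
    ecm = ecm_mle(counts, max_n)
    tirm = tirm_mle(counts, max_n, refine=False)
    lam = 2.0 * (tirm.loglik - ecm.loglik)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sim = _simulate_counts_ecm(rng, ecm.n_hat, counts.t)
        e = ecm_mle(sim, max_n)
        t_fit = tirm_mle(sim, max_n, refine=False)
        if 2.0 * (t_fit.loglik - e.loglik) >= lam - 1e-9:
            exceed += 1
    p = (exceed + 1) / (n_boot + 1)
    return ("TIRM" if p < 0.05 else "ECM"), p, lam


def bootstrap_ci(
    counts: CaptureCounts,
    model: str,
    max_n: int = 25,
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Percentile CI (2.5/97.5) from parametric bootstrap at the fitted
    parameters, holding the number of captures t fixed."""
    rng = np.random.default_rng(seed)
    estimates = []
    if model == "ECM":
        fit = ecm_mle(counts, max_n)
        for _ in range(n_boot):
            sim = _simulate_counts_ecm(rng, fit.n_hat, counts.t)
            estimates.append(ecm_mle(sim, max_n).n_hat)
    elif model == "TIRM":
        fit_t = tirm_mle(counts, max_n)
        for _ in range(n_boot):
            sim = _simulate_counts_tirm(rng, fit_t.n_hat, fit_t.n_easy,
                                        fit_t.alpha, counts.t)
            estimates.append(tirm_mle(sim, max_n, refine=False).n_hat)
    else:
        raise ValueError(f"unknown model {model!r}")
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)


def expected_r2_sample(s: float) -> float:
    """Sampling expectation of the composite r^2 at sample size S."""
    if s >= 30:
        return 1.0 / s + 3.19 / s ** 2
    return 0.0018 + 0.907 / s + 4.44 / s ** 2


def _ne_from_r2prime(r2p: float, s: float) -> float:
    if r2p <= 0:
        return math.inf
    if s >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2p, 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
    disc = max(0.308 ** 2 - 2.08 * r2p, 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2p)


@dataclass
class NeEstimate:
    ne_hat: float
    ci95: Tuple[float, float]
    r2_mean: float
    r2_expected: float
    s_harmonic: float
    n_comparisons: int


def ld_ne(
    genotypes: Dict[str, MultilocusGenotype],
    maf: float = 0.02,
) -> NeEstimate:
    """LD effective size from Burrows' composite disequilibrium.

    r^2 is computed for every allele pair across every locus pair (alleles
    below the MAF screen dropped), averaged with weights equal to the pair
    sample size; the parametric CI treats n' (the number of comparisons) as
    chi-square degrees of freedom.
    """
    inds = sorted(genotypes)
    loci = sorted({loc for g in genotypes.values() for loc in g})
    dosages: Dict[str, Dict[int, np.ndarray]] = {}
    for loc in loci:
        calls = [genotypes[i].get(loc) for i in inds]
        alleles = sorted({a for c in calls if c is not None for a in c})
        n_typed = sum(1 for c in calls if c is not None)
        if n_typed < 2:
            continue
        per_allele = {}
        for a in alleles:
            x = np.array([np.nan if c is None else float(c.count(a)) for c in calls])
            freq = np.nansum(x) / (2 * n_typed)
            if freq >= maf and freq <= 1 - maf:
                per_allele[a] = x
        if len(per_allele) >= 2:
            dosages[loc] = per_allele
    usable = sorted(dosages)
    if len(usable) < 2:
        raise ValueError("fewer than two usable polymorphic loci after MAF screen")

    r2_vals: List[float] = []
    weights: List[float] = []
    s_list: List[float] = []
    for l1, l2 in itertools.combinations(usable, 2):
        for a, xa in dosages[l1].items():
            for b, xb in dosages[l2].items():
                mask = ~np.isnan(xa) & ~np.isnan(xb)
                s = int(mask.sum())
                if s < 3:
                    continue
                va, vb = xa[mask], xb[mask]
                pa, pb = va.mean() / 2, vb.mean() / 2
                if min(pa, 1 - pa, pb, 1 - pb) <= 0:
                    continue
                delta = (np.mean(va * vb) / 2.0 - 2.0 * pa * pb) * s / (s - 1.0)
                # Weir's composite-correlation denominator includes the
                # within-locus Hardy-Weinberg disequilibrium terms
                d_a = float(np.mean(va == 2)) - pa ** 2
                d_b = float(np.mean(vb == 2)) - pb ** 2
                den = (pa * (1 - pa) + d_a) * (pb * (1 - pb) + d_b)
                if den <= 0:
                    continue
                r2 = delta ** 2 / den
                r2_vals.append(float(r2))
                weights.append(float(s))
                s_list.append(float(s))
    if not r2_vals:
        raise ValueError("no allele comparisons available")
    w = np.asarray(weights)
    r2_mean = float(np.average(r2_vals, weights=w))
    s_harm = float(len(s_list) / np.sum(1.0 / np.asarray(s_list)))
    e_r2 = expected_r2_sample(s_harm)
    ne_hat = _ne_from_r2prime(r2_mean - e_r2, s_harm)

    n_comp = len(r2_vals)
    r2_lo = n_comp * r2_mean / float(chi2_dist.ppf(0.975, n_comp))
    r2_hi = n_comp * r2_mean / float(chi2_dist.ppf(0.025, n_comp))
    ci = (_ne_from_r2prime(r2_hi - e_r2, s_harm),
          _ne_from_r2prime(r2_lo - e_r2, s_harm))
    return NeEstimate(ne_hat=ne_hat, ci95=ci, r2_mean=r2_mean,
                      r2_expected=e_r2, s_harmonic=s_harm,
                      n_comparisons=n_comp)


def ne_nc_ratio(ne: float, nc: float) -> float:
    """Effective-to-census size ratio."""
    if nc <= 0:
        raise ValueError("census size must be positive")
    return ne / nc
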