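"""Bottleneck detection: coalescent heterozygosity-excess tests under
IAM/TPM/SMM mutation models, an exact mid-p Wilcoxon signed-rank test,
the allele-frequency mode-shift check, and the M-ratio.

For each locus the equilibrium He distribution is obtained by simulating
coalescent genealogies of the sampled genes, placing mutations at a rate
tuned (by bisection on the expected allele count) so that datasets with
exactly the observed number of alleles can be collected by rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .identity import MultilocusGenotype

MODELS = ("IAM", "TPM", "SMM")
MC_THRESHOLD = 0.68  # critical M-ratio

TPM_SINGLE_STEP = 0.70
TPM_GEOM_MEAN = 2.8


def _sample_iam(rng: np.random.Generator, n: int, theta: float) -> np.ndarray:
    """Infinite-allele sample via the Ewens urn (exact coalescent marginal)."""
    u = rng.random(n)
    states = np.empty(n, dtype=np.int64)
    fresh = 0
    for i in range(n):
        if u[i] < theta / (theta + i):
            states[i] = fresh
            fresh += 1
        else:
            j = int(u[i] * (theta + i) - theta)  # uniform over previous genes
            states[i] = states[min(j, i - 1)]
    return states


def _sample_stepwise(rng: np.random.Generator, n: int, theta: float,
                     model: str) -> np.ndarray:
    """Microsatellite sample under SMM/TPM: coalescent tree, Poisson
    mutations placed by branch length, allele states in repeat units."""
    total = 2 * n - 1
    parent = [0] * total
    node_time = [0.0] * total
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        m = len(active)
        t += rng.exponential(2.0 / (m * (m - 1)))
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        if i < j:
            i, j = j, i
        a = active.pop(i)
        b = active.pop(j)
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active.append(nxt)
        nxt += 1
    lengths = [node_time[parent[v]] - node_time[v] for v in range(total - 1)]
    total_len = sum(lengths)
    n_mut = int(rng.poisson(theta / 2.0 * total_len))
    steps = [0] * total
    if n_mut:
        cum = np.cumsum(lengths)
        branches = np.searchsorted(cum, rng.random(n_mut) * total_len)
        if model == "SMM":
            sizes = np.ones(n_mut, dtype=np.int64)
        else:  # TPM: single step w.p. 0.70, else geometric multi-step
            sizes = np.where(rng.random(n_mut) < TPM_SINGLE_STEP, 1,
                             rng.geometric(1.0 / TPM_GEOM_MEAN, size=n_mut))
        signed = sizes * (rng.integers(0, 2, size=n_mut) * 2 - 1)
        for b, s in zip(branches, signed):
            steps[int(b)] += int(s)
    states = [0] * total
    for v in range(total - 2, -1, -1):  # parents always have higher index
        states[v] = states[parent[v]] + steps[v]
    return np.asarray(states[:n], dtype=np.int64)


def _sample_locus(rng: np.random.Generator, n: int, theta: float, model: str) -> np.ndarray:
    if model == "IAM":
        return _sample_iam(rng, n, theta)
    return _sample_stepwise(rng, n, theta, model)


def _unbiased_he(states: np.ndarray) -> float:
    n = states.size
    _, counts = np.unique(states, return_counts=True)
    p2 = float(np.sum((counts / n) ** 2))
    return n / (n - 1.0) * (1.0 - p2)


def _n_alleles(states: np.ndarray) -> int:
    return int(np.unique(states).size)


@lru_cache(maxsize=512)
def _theta_for_k(n_genes: int, k_alleles: int, model: str) -> float:
    """Bisection on theta so that the mean simulated allele count hits k.

    Deterministic per (n, k, model): the calibration uses its own fixed-seed
    generator, independent of the caller's stream.
    """
    if model == "IAM":
        # Ewens: E[k] = sum theta / (theta + i), solved directly
        def ek(theta: float) -> float:
            return float(np.sum(theta / (theta + np.arange(n_genes))))
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if ek(mid) < k_alleles:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)

    rng = np.random.default_rng(abs(hash((n_genes, k_alleles, model))) % (2 ** 32))
    batch = 150

    def mean_k(theta: float) -> float:
        return float(np.mean([_n_alleles(_sample_locus(rng, n_genes, theta, model))
                              for _ in range(batch)]))

    lo, hi = 1e-3, 1e4
    for _ in range(22):
        mid = math.sqrt(lo * hi)
        if mean_k(mid) < k_alleles:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_equilibrium_het(
    n_genes: int,
    k_alleles: int,
    model: str,
    n_iter: int = 1000,
    seed: int = 0,
    max_attempts: int = 100_000,
) -> np.ndarray:
    """Equilibrium He sample: coalescent datasets retained by rejection to
    exactly ``k_alleles`` observed alleles."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if not 2 <= k_alleles <= n_genes:
        raise ValueError("need 2 <= k_alleles <= n_genes")
    theta = _theta_for_k(n_genes, k_alleles, model)
    rng = np.random.default_rng(seed)
    out = np.empty(n_iter)
    got = 0
    attempts = 0
    while got < n_iter:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not collect {n_iter} datasets with k={k_alleles} "
                f"({model}, n={n_genes}) in {max_attempts} attempts; "
                f"theta={theta:.3g}, accepted={got}")
        states = _sample_locus(rng, n_genes, theta, model)
        if _n_alleles(states) == k_alleles:
            out[got] = _unbiased_he(states)
            got += 1
    return out


def wilcoxon_signed_rank_midp(differences: Sequence[float],
                              alternative: str = "greater") -> float:
    """Exact one-tailed mid-p signed-rank test by full sign enumeration.

    mid-p = P(W > w_obs) + 0.5 P(W = w_obs) under the 2^n equiprobable sign
    assignments on the ranks of |differences| (zeros dropped; ties take
    average ranks).  All-zero input returns 1.0.
    """
    d = np.asarray([x for x in differences if x != 0], dtype=float)
    if d.size == 0:
        return 1.0
    n = d.size
    if n > 25:
        raise ValueError("exact enumeration limited to n <= 25")
    if alternative == "less":
        d = -d
    elif alternative != "greater":
        raise ValueError("alternative must be 'greater' or 'less'")
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    scaled = np.round(ranks * 2).astype(np.int64)  # average ranks -> integers
    w_obs = int(np.sum(scaled[d > 0]))
    # distribution of the positive-rank sum via DP over 2^n assignments
    max_w = int(scaled.sum())
    dist = np.zeros(max_w + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:max_w + 1 - r]
        dist = 0.5 * (dist + shifted)
    p_gt = float(dist[w_obs + 1:].sum())
    p_eq = float(dist[w_obs])
    return p_gt + 0.5 * p_eq


@dataclass
class LocusExcess:
    locus: str
    k_alleles: int
    n_genes: int
    he_obs: float
    he_eq_mean: float
    he_eq_sd: float
    dh: float
    dh_std: Optional[float]
    p_excess_eq: float  # P(equilibrium locus shows excess)


@dataclass
class HetExcessResult:
    model: str
    loci: List[LocusExcess]
    n_excess_observed: int
    n_excess_expected: float
    wilcoxon_p: float
    excluded_loci: List[str]


def _allele_counts(genotypes: Dict[str, MultilocusGenotype]
                   ) -> Dict[str, Dict[int, int]]:
    counts: Dict[str, Dict[int, int]] = {}
    for g in genotypes.values():
        for loc, call in g.items():
            if call is None:
                continue
            d = counts.setdefault(loc, {})
            for a in call:
                d[a] = d.get(a, 0) + 1
    return counts


def het_excess_test(
    genotypes: Dict[str, MultilocusGenotype],
    model: str,
    n_iter: int = 1000,
    seed: int = 0,
) -> HetExcessResult:
    """Per-locus heterozygosity excess against the coalescent equilibrium
    expectation, with a one-tailed exact mid-p Wilcoxon over loci."""
    counts = _allele_counts(genotypes)
    loci = sorted(counts)
    excluded = [loc for loc in loci if len(counts[loc]) < 2]
    usable = [loc for loc in loci if loc not in excluded]
    if len(usable) < 4:
        raise ValueError("need at least four polymorphic loci")

    rows = []
    for i, loc in enumerate(usable):
        d = counts[loc]
        n = sum(d.values())
        k = len(d)
        he_obs = n / (n - 1.0) * (1.0 - sum((c / n) ** 2 for c in d.values()))
        he_eq = simulate_equilibrium_het(n, k, model, n_iter=n_iter,
                                         seed=seed + 1000 * i)
        mean, sd = float(he_eq.mean()), float(he_eq.std(ddof=1))
        dh = he_obs - mean
        rows.append(LocusExcess(
            locus=loc, k_alleles=k, n_genes=n, he_obs=he_obs,
            he_eq_mean=mean, he_eq_sd=sd, dh=dh,
            dh_std=dh / sd if sd > 0 else None,
            p_excess_eq=float(np.mean(he_eq > mean))))

    diffs = [r.dh_std if r.dh_std is not None else r.dh for r in rows]
    return HetExcessResult(
        model=model,
        loci=rows,
        n_excess_observed=sum(1 for r in rows if r.dh > 0),
        n_excess_expected=float(sum(r.p_excess_eq for r in rows)),
        wilcoxon_p=wilcoxon_signed_rank_midp(diffs, alternative="greater"),
        excluded_loci=excluded,
    )


def mode_shift(allele_freqs: Dict[str, Dict[int, float]]) -> str:
    """Pool allele frequencies across loci into ten 0.1-wide classes;
    'L-shaped' iff the lowest class (0, 0.1] is strictly modal."""
    pooled = [f for fr in allele_freqs.values() for f in fr.values() if f > 0]
    if not pooled:
        raise ValueError("no alleles to pool")
    bins = np.zeros(10, dtype=int)
    for f in pooled:
        idx = min(int(math.ceil(f * 10)) - 1, 9)
        bins[max(idx, 0)] += 1
    return "L-shaped" if bins[0] > bins[1:].max() else "shifted"


def m_ratio(
    allele_sizes: Dict[str, Sequence[int]],
    repeat_units: Dict[str, int],
) -> Tuple[Dict[str, float], float, List[str]]:
    """Garza-Williamson M = k / (r + 1), r = size range in repeat units.

    Returns (per-locus M, mean M, flags for imperfect ladders).  Loci with a
    single allele are skipped; a zero repeat unit is rejected.
    """
    per_locus: Dict[str, float] = {}
    flags: List[str] = []
    for loc, sizes in sorted(allele_sizes.items()):
        unit = repeat_units.get(loc)
        if unit is None or unit <= 0:
            raise ValueError(f"repeat unit for {loc} must be a positive integer")
        uniq = sorted(set(sizes))
        if len(uniq) < 2:
            continue
        span = uniq[-1] - uniq[0]
        if span % unit != 0:
            flags.append(f"{loc}: allele range {span} not a multiple of unit {unit}; rounded")
        r = round(span / unit)
        per_locus[loc] = len(uniq) / (r + 1.0)
    if not per_locus:
        raise ValueError("no locus with >= 2 alleles")
    mean = float(np.mean(list(per_locus.values())))
    return per_locus, mean, flags
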